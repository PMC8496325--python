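import pytest

from synorth.errors import DataError
from synorth.formats_io import (
    CollinearityFile,
    NameMap,
    OrthogroupTable,
    RawBlock,
    TandemFile,
    read_collinearity,
    read_gene_positions,
    read_orthogroups,
    read_ploidy,
    read_tandem,
    translate_gff,
    write_collinearity,
    write_gene_positions,
    write_orthogroups,
    write_tandem,
)

NAME_MAP = NameMap(
    species_index={"spA": 0, "spB": 1},
    orig_to_canon={"a1": "0_0", "a2": "0_1", "a3": "0_2", "b1": "1_0", "b2": "1_1"},
)


# --- orthogroups ------------------------------------------------------------


def test_read_orthogroups_parses_comma_lists(tmp_path):
    path = tmp_path / "og.tsv"
    path.write_text("Orthogroup\tspA\tspB\nOG1\ta1, a2\tb1\nOG2\ta3\t\n")
    table = read_orthogroups(path, NAME_MAP)
    assert table.species == ["spA", "spB"]
    og1 = dict(table.groups)["OG1"]
    assert og1 == {"spA": ["0_0", "0_1"], "spB": ["1_0"]}
    # empty cell yields an empty list
    assert dict(table.groups)["OG2"]["spB"] == []


def test_read_orthogroups_duplicate_gene_names_both_groups(tmp_path):
    path = tmp_path / "og.tsv"
    path.write_text("Orthogroup\tspA\tspB\nOG1\ta1\tb1\nOG2\ta1\tb2\n")
    with pytest.raises(DataError, match="OG1") as err:
        read_orthogroups(path, NAME_MAP)
    assert "OG2" in str(err.value)


def test_read_orthogroups_unknown_species_column(tmp_path):
    path = tmp_path / "og.tsv"
    path.write_text("Orthogroup\tspA\tspZ\nOG1\ta1\tb1\n")
    with pytest.raises(DataError, match="spZ"):
        read_orthogroups(path, NAME_MAP)


# --- collinearity -----------------------------------------------------------


def _collinearity_text():
    lines = [
        "############### Parameters ###############",
        "# MATCH_SCORE: 50",
        "## Alignment 0: score=150 e_value=0 N=3 cA1&cB1 plus",
    ]
    for i in range(3):
        lines.append(f"0-{i}:\t0_{i}\t1_{i}\t1e-50")
    lines.append("## Alignment 1: score=250 e_value=0 N=5 cA2&cB2 minus")
    for i in range(5):
        lines.append(f"1-{i}:\t0_{10 + i}\t1_{10 + i}\t1e-50")
    return "\n".join(lines) + "\n"


def test_read_collinearity_blocks_in_order(tmp_path):
    path = tmp_path / "x.collinearity"
    path.write_text(_collinearity_text())
    cf = read_collinearity(path)
    assert [len(b) for b in cf.blocks] == [3, 5]
    assert cf.blocks[0].orientation == "plus"
    assert cf.blocks[1].orientation == "minus"
    assert cf.blocks[0].pairs[0] == ("0_0", "1_0", 1e-50)
    assert not cf.blocks[0].is_intra


def test_read_collinearity_intra_genome_flag(tmp_path):
    path = tmp_path / "x.collinearity"
    path.write_text(
        "## Alignment 0: score=100 e_value=0 N=2 cA1&cA2 plus\n"
        "0-0:\t0_0\t0_5\t1e-10\n0-1:\t0_1\t0_6\t1e-10\n"
    )
    cf = read_collinearity(path)
    assert cf.blocks[0].is_intra


def test_read_collinearity_missing_evalue_is_fatal_with_line(tmp_path):
    path = tmp_path / "x.collinearity"
    path.write_text(
        "## Alignment 0: score=100 e_value=0 N=2 cA1&cB1 plus\n"
        "0-0:\t0_0\t1_0\t1e-10\n0-1:\t0_1\t1_1\n"
    )
    with pytest.raises(DataError, match=":3"):
        read_collinearity(path)


def test_read_collinearity_empty_block_skipped_with_warning(tmp_path, caplog):
    path = tmp_path / "x.collinearity"
    path.write_text(
        "## Alignment 0: score=0 e_value=0 N=0 cA1&cB1 plus\n"
        "## Alignment 1: score=100 e_value=0 N=2 cA1&cB1 plus\n"
        "1-0:\t0_0\t1_0\t1e-10\n1-1:\t0_1\t1_1\t1e-10\n"
    )
    with caplog.at_level("WARNING", logger="synorth"):
        cf = read_collinearity(path)
    assert [b.block_id for b in cf.blocks] == ["1"]
    assert any("no gene pairs" in r.message for r in caplog.records)


# --- tandem -----------------------------------------------------------------


def test_read_tandem_pairs(tmp_path):
    path = tmp_path / "x.tandem"
    path.write_text("0_0,0_1\n0_1,0_2\n")
    tf = read_tandem(path)
    assert tf.pairs == [("0_0", "0_1"), ("0_1", "0_2")]


def test_read_tandem_cross_species_pair_fatal(tmp_path):
    path = tmp_path / "x.tandem"
    path.write_text("0_0,1_0\n")
    with pytest.raises(DataError, match="spans two species"):
        read_tandem(path)


def test_read_tandem_self_pair_fatal(tmp_path):
    path = tmp_path / "x.tandem"
    path.write_text("0_0,0_0\n")
    with pytest.raises(DataError, match="self-pair"):
        read_tandem(path)


# --- ploidy -----------------------------------------------------------------


def test_ploidy_defaults_to_one_when_absent():
    assert read_ploidy(None, ["spA", "spB"]) == {"spA": 1, "spB": 1}


def test_ploidy_reads_multipliers_and_rejects_zero(tmp_path):
    path = tmp_path / "ploidy.tsv"
    path.write_text("spB\t2\n")
    assert read_ploidy(path, ["spA", "spB"]) == {"spA": 1, "spB": 2}
    path.write_text("spA\t0\n")
    with pytest.raises(DataError, match=">= 1"):
        read_ploidy(path, ["spA", "spB"])


# --- translate_gff ----------------------------------------------------------


def _write_species(tmp_path, label, genes):
    """genes: (chrom, gid, start, end) rows, written unsorted on purpose."""
    gff = tmp_path / f"{label}.gff3"
    lines = ["##gff-version 3"]
    for chrom, gid, start, end in genes:
        lines.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
    gff.write_text("\n".join(lines) + "\n")
    fasta = tmp_path / f"{label}.fasta"
    fasta.write_text("".join(f">{g[1]}\nMKV\n" for g in genes))
    return gff, fasta


def test_translate_gff_emits_sorted_positions_and_bijection(tmp_path):
    gff_a, fa_a = _write_species(
        tmp_path, "spA", [("c1", "a2", 2001, 2900), ("c1", "a1", 1, 900), ("c1", "a3", 4001, 4900)]
    )
    gff_b, fa_b = _write_species(tmp_path, "spB", [("c1", "b1", 1, 900), ("c1", "b2", 2001, 2900)])
    positions, fasta_out, name_map = translate_gff(
        [gff_a, gff_b], [fa_a, fa_b], tmp_path / "out", species_labels=["spA", "spB"]
    )
    rows = [l.split("\t") for l in positions.read_text().splitlines()]
    # sorted by chromosome then start despite shuffled GFF input
    starts = [int(r[2]) for r in rows[:3]]
    assert starts == sorted(starts)
    # bijection: distinct species indices, gene indices restart per species
    assert name_map.orig_to_canon["a1"] == "0_0"
    assert name_map.orig_to_canon["a2"] == "0_1"
    assert name_map.orig_to_canon["b1"] == "1_0"
    assert len(set(name_map.orig_to_canon.values())) == len(name_map.orig_to_canon)
    # FASTA renamed with the identical bijection
    headers = [l[1:] for l in fasta_out.read_text().splitlines() if l.startswith(">")]
    assert headers == ["0_0", "0_1", "0_2", "1_0", "1_1"]
    # back-translation restores the original IDs
    assert [name_map.to_original(h) for h in headers] == ["a1", "a2", "a3", "b1", "b2"]


def test_translate_gff_orphan_fasta_record_excluded(tmp_path, caplog):
    gff, fa = _write_species(tmp_path, "spA", [("c1", "a1", 1, 900)])
    fa.write_text(">a1\nMKV\n>ghost\nMKV\n")
    with caplog.at_level("WARNING", logger="synorth"):
        _, fasta_out, _ = translate_gff([gff], [fa], tmp_path / "out")
    headers = [l for l in fasta_out.read_text().splitlines() if l.startswith(">")]
    assert headers == [">0_0"]
    assert any("ghost" in r.message for r in caplog.records)


def test_translate_gff_duplicate_gene_id_fatal(tmp_path):
    gff, fa = _write_species(
        tmp_path, "spA", [("c1", "a1", 1, 900), ("c2", "a1", 1, 900)]
    )
    with pytest.raises(DataError):
        translate_gff([gff], [fa], tmp_path / "out")


# --- round trips ------------------------------------------------------------


def test_collinearity_round_trip(tmp_path):
    blocks = [
        RawBlock("0", "cA1", "cB1", "plus", "0", "1", [("0_0", "1_0", 1e-10), ("0_1", "1_1", 0.0)], 100.0),
        RawBlock("1", "cA2", "cB2", "minus", "0", "1", [("0_5", "1_9", 2e-30)] * 1, 50.0),
    ]
    cf = CollinearityFile(blocks=blocks)
    path = tmp_path / "x.collinearity"
    write_collinearity(cf, path)
    again = read_collinearity(path)
    assert [b.pairs for b in again.blocks] == [b.pairs for b in blocks]
    # writing what was read reproduces the file byte-identically
    path2 = tmp_path / "y.collinearity"
    write_collinearity(again, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_orthogroups_round_trip(tmp_path):
    table = OrthogroupTable(
        species=["spA", "spB"],
        groups=[("OG1", {"spA": ["0_0", "0_1"], "spB": ["1_0"]}), ("OG2", {"spA": ["0_2"], "spB": []})],
    )
    path = tmp_path / "og.tsv"
    write_orthogroups(table, path)
    again = read_orthogroups(path)
    assert again.species == table.species
    assert again.groups == table.groups


def test_tandem_round_trip(tmp_path):
    tf = TandemFile(pairs=[("0_0", "0_1"), ("1_3", "1_4")])
    path = tmp_path / "x.tandem"
    write_tandem(tf, path)
    assert read_tandem(path).pairs == tf.pairs


def test_positions_and_name_map_round_trip(tmp_path, two_species_registry):
    nm = NameMap(
        species_index={"spA": 0, "spB": 1},
        orig_to_canon={f"{s}{i}": f"{j}_{i}" for j, s in enumerate("ab") for i in range(5)},
    )
    pos = tmp_path / "genes.gff"
    write_gene_positions(two_species_registry, pos)
    reg = read_gene_positions(pos, nm)
    assert set(reg.records) == set(two_species_registry.records)
    assert reg.species == ["spA", "spB"]
    nm_path = tmp_path / "nm.tsv"
    nm.write(nm_path)
    again = NameMap.read(nm_path)
    assert again.orig_to_canon == nm.orig_to_canon
    assert again.species_index == nm.species_index
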