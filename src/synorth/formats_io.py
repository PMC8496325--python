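"""Readers and writers for every external file format the pipeline touches.

The pipeline consumes OrthoFinder-style orthogroup tables, MCScanX-style
``.collinearity`` and ``.tandem`` files, and a four-column gene position
table (the MCScanX ``gff`` dialect).  Gene names inside the MCScanX files
are *canonical* names of the form ``<speciesIndex>_<geneIndex>``; the
:func:`translate_gff` utility produces that naming from ordinary GFF3 and
protein FASTA inputs, together with a translation table so every result
can be mapped back to the original annotation IDs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from synorth.errors import DataError

log = logging.getLogger("synorth")

_CANONICAL_RE = re.compile(r"^(\d+)_(\d+)$")


def canonical_species_index(name: str) -> int:
    """Species index encoded in a canonical gene name ``<sp>_<gene>``."""
    m = _CANONICAL_RE.match(name)
    if m is None:
        raise DataError(f"gene name {name!r} is not in canonical <species>_<gene> form")
    return int(m.group(1))


def _canonical_sort_key(name: str):
    m = _CANONICAL_RE.match(name)
    if m is None:
        return (1, name, 0)
    return (0, int(m.group(1)), int(m.group(2)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic location and both of its names.

    Coordinates are GFF3-style 1-based inclusive.  ``canonical_name`` is
    the translated ``<speciesIndex>_<geneIndex>`` identifier used in all
    MCScanX-dialect files; the mapping to ``original_name`` is a bijection
    across the whole analysis.
    """

    species_id: str
    chrom: str
    start: int
    end: int
    original_name: str
    canonical_name: str

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(
                f"gene {self.original_name}: start {self.start} > end {self.end}"
            )


class GeneRegistry:
    """All genes of the analysis, with per-chromosome gene order.

    Gene order within a chromosome is ascending start coordinate, ties
    broken by end then canonical name.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.canonical_name in self.records:
                raise DataError(f"duplicate canonical gene name {rec.canonical_name}")
            self.records[rec.canonical_name] = rec
        self._order: dict[tuple[str, str], list[str]] = {}
        by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
        for rec in self.records.values():
            by_chrom.setdefault((rec.species_id, rec.chrom), []).append(rec)
        self._ordinal: dict[str, int] = {}
        for key, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.start, r.end, r.canonical_name))
            names = [r.canonical_name for r in recs]
            self._order[key] = names
            for i, n in enumerate(names):
                self._ordinal[n] = i
        self.species: list[str] = sorted({r.species_id for r in self.records.values()})

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __len__(self) -> int:
        return len(self.records)

    def record(self, gene: str) -> GeneRecord:
        try:
            return self.records[gene]
        except KeyError:
            raise DataError(f"unknown gene {gene!r}") from None

    def species_of(self, gene: str) -> str:
        return self.record(gene).species_id

    def chromosome_order(self, species_id: str, chrom: str) -> list[str]:
        return self._order.get((species_id, chrom), [])

    def chromosomes(self) -> list[tuple[str, str]]:
        return sorted(self._order)

    def ordinal(self, gene: str) -> int:
        """Position of the gene within its chromosome's gene order."""
        self.record(gene)
        return self._ordinal[gene]


@dataclass
class NameMap:
    """Bijective translation between annotation IDs and canonical names."""

    species_index: dict[str, int]
    orig_to_canon: dict[str, str]
    canon_to_orig: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.canon_to_orig:
            self.canon_to_orig = {c: o for o, c in self.orig_to_canon.items()}
        if len(self.canon_to_orig) != len(self.orig_to_canon):
            raise DataError("gene name translation is not a bijection")

    def species_label(self, index: int) -> str:
        for label, i in self.species_index.items():
            if i == index:
                return label
        raise DataError(f"unknown species index {index}")

    def to_canonical(self, original: str) -> str:
        try:
            return self.orig_to_canon[original]
        except KeyError:
            raise DataError(f"gene {original!r} has no canonical translation") from None

    def to_original(self, canonical: str) -> str:
        try:
            return self.canon_to_orig[canonical]
        except KeyError:
            raise DataError(f"canonical name {canonical!r} is not in the translation table") from None

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for label, idx in sorted(self.species_index.items(), key=lambda kv: kv[1]):
                fh.write(f"#species\t{idx}\t{label}\n")
            for orig, canon in sorted(
                self.orig_to_canon.items(), key=lambda kv: _canonical_sort_key(kv[1])
            ):
                fh.write(f"{canon}\t{orig}\n")

    @classmethod
    def read(cls, path: str | Path) -> "NameMap":
        species: dict[str, int] = {}
        orig_to_canon: dict[str, str] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if line.startswith("#species"):
                    if len(fields) != 3:
                        raise DataError(f"{path}:{lineno}: malformed species line")
                    species[fields[2]] = int(fields[1])
                    continue
                if len(fields) != 2:
                    raise DataError(f"{path}:{lineno}: malformed translation line")
                canon, orig = fields
                if orig in orig_to_canon:
                    raise DataError(f"{path}:{lineno}: gene {orig!r} translated twice")
                orig_to_canon[orig] = canon
        return cls(species_index=species, orig_to_canon=orig_to_canon)

    @classmethod
    def from_orthofinder(
        cls, sequence_ids: str | Path, species_ids: str | Path
    ) -> "NameMap":
        """Build a translation from OrthoFinder ``SequenceIDs.txt``/``SpeciesIDs.txt``."""
        species: dict[str, int] = {}
        with Path(species_ids).open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                idx, label = line.split(":", 1)
                label = Path(label.strip()).stem  # strip the .fa/.fasta suffix
                species[label] = int(idx)
        orig_to_canon: dict[str, str] = {}
        with Path(sequence_ids).open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                canon, orig = line.split(":", 1)
                orig_to_canon[orig.strip()] = canon.strip()
        return cls(species_index=species, orig_to_canon=orig_to_canon)


@dataclass
class OrthogroupTable:
    """Ordered orthogroups: (group id, species label -> canonical gene list)."""

    species: list[str]
    groups: list[tuple[str, dict[str, list[str]]]]

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class TandemFile:
    """Unordered tandem-duplicate gene pairs (canonical names)."""

    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RawBlock:
    """One MCScanX collinearity alignment: an ordered run of gene pairs."""

    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" or "minus"
    species_a: str  # species index (as string) of every gene_a
    species_b: str
    pairs: list[tuple[str, str, float]]
    score: float = 0.0

    @property
    def is_intra(self) -> bool:
        return self.species_a == self.species_b

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CollinearityFile:
    blocks: list[RawBlock]

    def __len__(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_gene_positions(path: str | Path, name_map: NameMap | None = None) -> GeneRegistry:
    """Read the four-column gene position table (chrom, name, start, end).

    Gene names must be canonical.  Species labels are resolved through
    ``name_map`` when given, otherwise the bare species index is used as
    the label.
    """
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, canon, start, end = fields
            idx = canonical_species_index(canon)
            species = name_map.species_label(idx) if name_map else str(idx)
            orig = name_map.to_original(canon) if name_map else canon
            records.append(
                GeneRecord(
                    species_id=species,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    original_name=orig,
                    canonical_name=canon,
                )
            )
    return GeneRegistry(records)


def write_gene_positions(registry: GeneRegistry, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for species, chrom in registry.chromosomes():
            for gene in registry.chromosome_order(species, chrom):
                rec = registry.record(gene)
                fh.write(f"{rec.chrom}\t{rec.canonical_name}\t{rec.start}\t{rec.end}\n")


def read_orthogroups(path: str | Path, name_map: NameMap | None = None) -> OrthogroupTable:
    """Parse an OrthoFinder-style ``Orthogroups.tsv`` table.

    The header row names the species columns.  Cells are comma-separated
    gene lists (empty cells yield empty lists).  When ``name_map`` is
    given, gene names are translated to canonical form; the species
    columns must then all be known to the map.  A gene listed in two
    groups is a fatal error: orthogroups must partition their genes.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataError(f"{path}: empty orthogroups file")
        columns = header.split("\t")
        species = columns[1:]
        if name_map is not None:
            unknown = [s for s in species if s not in name_map.species_index]
            if unknown:
                raise DataError(
                    f"{path}: unknown species column(s): {', '.join(unknown)}"
                )
        groups: list[tuple[str, dict[str, list[str]]]] = []
        seen: dict[str, str] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise DataError(
                    f"{path}:{lineno}: row has {len(cells)} cells, header has {len(columns)}"
                )
            og_id = cells[0]
            members: dict[str, list[str]] = {}
            for sp, cell in zip(species, cells[1:]):
                genes = [g.strip() for g in cell.split(",") if g.strip()]
                if name_map is not None:
                    genes = [name_map.to_canonical(g) for g in genes]
                for g in genes:
                    if g in seen:
                        raise DataError(
                            f"{path}: gene {g!r} appears in both {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id
                members[sp] = genes
            groups.append((og_id, members))
    return OrthogroupTable(species=list(species), groups=groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og_id, members in table.groups:
            cells = [", ".join(members.get(sp, [])) for sp in table.species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


_ALIGNMENT_RE = re.compile(
    r"^##\s*Alignment\s+(\S+?):\s*score=(\S+)\s+e_value=(\S+)\s+N=(\d+)\s+(\S+)&(\S+)\s+(plus|minus)\s*$"
)


def read_collinearity(path: str | Path) -> CollinearityFile:
    """Parse an MCScanX ``.collinearity`` file.

    Comment lines (``#``) are skipped; ``## Alignment`` headers open a
    block; every following pair line contributes one (gene_a, gene_b,
    e-value) tuple.  Blocks are returned in file order with pair order
    preserved.  A block whose gene_a genes come from one species and
    gene_b genes from the same species is an intra-genome block.
    """
    path = Path(path)
    blocks: list[RawBlock] = []
    seen_ids: set[str] = set()
    current: RawBlock | None = None

    def _finish(block: RawBlock | None):
        if block is None:
            return
        if not block.pairs:
            log.warning("collinearity block %s has no gene pairs; skipped", block.block_id)
            return
        sp_a = {canonical_species_index(ga) for ga, _, _ in block.pairs}
        sp_b = {canonical_species_index(gb) for _, gb, _ in block.pairs}
        if len(sp_a) != 1 or len(sp_b) != 1:
            raise DataError(
                f"{path}: block {block.block_id} mixes genes from several species on one side"
            )
        block.species_a = str(sp_a.pop())
        block.species_b = str(sp_b.pop())
        blocks.append(block)

    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _ALIGNMENT_RE.match(line)
            if m:
                _finish(current)
                block_id = m.group(1)
                if block_id in seen_ids:
                    raise DataError(f"{path}:{lineno}: duplicate block id {block_id}")
                seen_ids.add(block_id)
                current = RawBlock(
                    block_id=block_id,
                    chrom_a=m.group(5),
                    chrom_b=m.group(6),
                    orientation=m.group(7),
                    species_a="",
                    species_b="",
                    pairs=[],
                    score=float(m.group(2)),
                )
                continue
            if line.startswith("#"):
                continue
            if current is None:
                raise DataError(f"{path}:{lineno}: gene pair outside any alignment block")
            if ":" not in line:
                raise DataError(f"{path}:{lineno}: malformed gene pair line")
            _, rest = line.split(":", 1)
            fields = rest.split()
            if len(fields) != 3:
                raise DataError(
                    f"{path}:{lineno}: expected gene_a, gene_b, e_value after ':'"
                )
            ga, gb, ev = fields
            try:
                e_value = float(ev)
            except ValueError:
                raise DataError(f"{path}:{lineno}: bad e-value {ev!r}") from None
            if e_value < 0:
                raise DataError(f"{path}:{lineno}: negative e-value")
            current.pairs.append((ga, gb, e_value))
    _finish(current)
    return CollinearityFile(blocks=blocks)


def write_collinearity(cf: CollinearityFile, path: str | Path) -> None:
    """Write blocks back out in the MCScanX dialect (round-trip safe)."""
    with Path(path).open("w") as fh:
        fh.write("############### Statistics ###############\n")
        fh.write(f"# Number of collinear blocks: {len(cf.blocks)}\n")
        for block in cf.blocks:
            fh.write(
                f"## Alignment {block.block_id}: score={block.score:g} e_value=0 "
                f"N={len(block.pairs)} {block.chrom_a}&{block.chrom_b} {block.orientation}\n"
            )
            for i, (ga, gb, ev) in enumerate(block.pairs):
                fh.write(f"{block.block_id}-{i}:\t{ga}\t{gb}\t{ev:g}\n")


def read_tandem(path: str | Path, registry: GeneRegistry | None = None) -> TandemFile:
    """Parse an MCScanX ``.tandem`` file of comma-separated gene pairs.

    Both members of a pair must come from the same species (same
    canonical species index); with a registry, the same chromosome too.
    Self-pairs are rejected.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes = [g.strip() for g in line.split(",") if g.strip()]
            if len(genes) % 2 != 0:
                raise DataError(f"{path}:{lineno}: odd number of gene names")
            for ga, gb in zip(genes[::2], genes[1::2]):
                if ga == gb:
                    raise DataError(f"{path}:{lineno}: self-pair {ga!r}")
                if canonical_species_index(ga) != canonical_species_index(gb):
                    raise DataError(
                        f"{path}:{lineno}: tandem pair {ga},{gb} spans two species"
                    )
                if registry is not None:
                    ra, rb = registry.record(ga), registry.record(gb)
                    if ra.chrom != rb.chrom:
                        raise DataError(
                            f"{path}:{lineno}: tandem pair {ga},{gb} spans two chromosomes"
                        )
                pairs.append((ga, gb))
    return TandemFile(pairs=pairs)


def write_tandem(tf: TandemFile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ga, gb in tf.pairs:
            fh.write(f"{ga},{gb}\n")


def read_ploidy(path: str | Path | None, species: Sequence[str]) -> dict[str, int]:
    """Read the optional relative-ploidy table; absent file means 1 everywhere.

    The file is tab- or whitespace-separated ``species  multiplier`` rows;
    species not listed default to 1.  All multipliers must be >= 1.
    """
    ploidy = {sp: 1 for sp in species}
    if path is None:
        return ploidy
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 'species ploidy'")
            sp, mult = fields
            if sp not in ploidy:
                raise DataError(f"{path}:{lineno}: unknown species {sp!r}")
            value = int(mult)
            if value < 1:
                raise DataError(f"{path}:{lineno}: ploidy must be >= 1")
            ploidy[sp] = value
    return ploidy


# ---------------------------------------------------------------------------
# GFF/FASTA translation
# ---------------------------------------------------------------------------


def _genes_from_gff(path: Path) -> list[tuple[str, str, int, int]]:
    """(chrom, gene_id, start, end) for every gene feature, via gffutils."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate IDs
        raise DataError(f"{path}: cannot parse GFF3 ({exc})") from exc
    genes = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise DataError(f"{path}: duplicate gene ID {gid!r}")
        seen.add(gid)
        genes.append((feat.seqid, gid, feat.start, feat.end))
    return genes


def translate_gff(
    gff_paths: Sequence[str | Path],
    fasta_paths: Sequence[str | Path],
    out_dir: str | Path,
    species_labels: Sequence[str] | None = None,
) -> tuple[Path, Path, NameMap]:
    """Convert GFF3 + protein FASTA inputs to the canonical naming scheme.

    One GFF3 and one FASTA per species, in matching order.  Writes to
    ``out_dir``: a combined four-column gene position table
    (``genes.gff``), a combined renamed protein FASTA
    (``proteins.fasta``), and the translation table (``name_map.tsv``).

    Species indices follow input order; gene indices restart at 0 for
    each species and follow chromosomal order (ascending start within a
    chromosome).  A FASTA record with no matching gene is excluded with
    a warning; a duplicate gene ID within a GFF is fatal.
    """
    if len(gff_paths) != len(fasta_paths):
        raise DataError("need exactly one FASTA per GFF3")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if species_labels is None:
        species_labels = [Path(p).stem for p in gff_paths]
    if len(set(species_labels)) != len(species_labels):
        raise DataError("species labels are not unique")

    species_index = {label: i for i, label in enumerate(species_labels)}
    orig_to_canon: dict[str, str] = {}
    records: list[GeneRecord] = []
    for sp_idx, (label, gff_path) in enumerate(zip(species_labels, gff_paths)):
        genes = _genes_from_gff(Path(gff_path))
        genes.sort(key=lambda g: (g[0], g[2], g[3], g[1]))
        for gene_idx, (chrom, gid, start, end) in enumerate(genes):
            if gid in orig_to_canon:
                raise DataError(f"gene ID {gid!r} occurs in more than one genome")
            canon = f"{sp_idx}_{gene_idx}"
            orig_to_canon[gid] = canon
            records.append(
                GeneRecord(
                    species_id=label,
                    chrom=chrom,
                    start=start,
                    end=end,
                    original_name=gid,
                    canonical_name=canon,
                )
            )
    name_map = NameMap(species_index=species_index, orig_to_canon=orig_to_canon)
    registry = GeneRegistry(records)

    positions_path = out_dir / "genes.gff"
    write_gene_positions(registry, positions_path)

    fasta_out = out_dir / "proteins.fasta"
    renamed: list[SeqRecord] = []
    for fasta_path in fasta_paths:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            canon = orig_to_canon.get(rec.id)
            if canon is None:
                log.warning(
                    "FASTA record %s has no gene in any GFF3; excluded", rec.id
                )
                continue
            renamed.append(SeqRecord(Seq(str(rec.seq)), id=canon, description=""))
    renamed.sort(key=lambda r: _canonical_sort_key(r.id))
    SeqIO.write(renamed, str(fasta_out), "fasta")

    map_path = out_dir / "name_map.tsv"
    name_map.write(map_path)
    return positions_path, fasta_out, name_map
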