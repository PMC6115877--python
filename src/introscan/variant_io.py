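"""Read four-taxon variant data and polarize it by the outgroup.

Three entry points produce the same in-memory representation, one
:class:`PolarizedSiteTable` per scaffold:

* :func:`read_vcf` — a combined VCF with one sample per taxon (haploid GTs
  for single-genome assemblies; diploid dosages are supported);
* :func:`read_aligned_fasta` — a four-row alignment of one scaffold;
* :func:`read_snp_table` — a simple TSV dialect (scaffold, pos, one allele
  column per taxon) of the kind produced by whole-genome aligners'
  show-snps style reports.

Polarization: the outgroup allele defines "ancestral"; the derived-allele
frequency of each taxon is its frequency of the non-outgroup allele, so
p4 = 0 at every retained site under strict polarization.  Sites that are
monomorphic across the quartet, carry more than two alleles, have missing
calls, or cannot be polarized are dropped, never imputed; each drop reason
is counted and logged.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "InputError",
    "QuartetConfig",
    "PolarizedSite",
    "PolarizedSiteTable",
    "DropCounts",
    "read_vcf",
    "read_aligned_fasta",
    "read_snp_table",
    "write_snp_table",
]

_VALID_BASES = frozenset(b"ACGT")


class ConfigurationError(ValueError):
    """A quartet/sample configuration problem (e.g. a sample not in the input)."""


class InputError(ValueError):
    """A malformed or out-of-contract input file."""


@dataclass(frozen=True)
class QuartetConfig:
    """Maps the quartet roles (P1, P2, P3, outgroup) onto input sample names.

    ``sample_map`` translates a taxon label to the sample/record identifier
    used in the input; labels map to themselves by default.
    """

    p1_label: str
    p2_label: str
    p3_label: str
    outgroup_label: str
    sample_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = self.labels
        if len(set(labels)) != 4:
            raise ConfigurationError(f"quartet labels must be distinct: {labels}")

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.p1_label, self.p2_label, self.p3_label, self.outgroup_label)

    @property
    def samples(self) -> tuple[str, str, str, str]:
        """Input sample identifiers in (P1, P2, P3, O) order."""
        return tuple(self.sample_map.get(lab, lab) for lab in self.labels)

    @classmethod
    def from_string(cls, spec: str) -> "QuartetConfig":
        """Parse 'P1,P2,P3,O' (sample names double as labels)."""
        parts = [s.strip() for s in spec.split(",")]
        if len(parts) != 4:
            raise ConfigurationError(
                f"quartet must name exactly four taxa, got {spec!r}"
            )
        return cls(*parts)


@dataclass(frozen=True)
class PolarizedSite:
    """One biallelic site with per-taxon derived-allele frequencies."""

    scaffold: str
    pos: int  # 1-based
    p1: float
    p2: float
    p3: float
    p4: float


@dataclass
class DropCounts:
    """Counts of sites dropped per reason during polarization."""

    counts: Counter = field(default_factory=Counter)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] += n

    def __getitem__(self, reason: str) -> int:
        return self.counts[reason]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return dict(self.counts)

    def log_summary(self, source: str) -> None:
        if self.total:
            logger.info(
                "%s: dropped %d sites (%s)",
                source,
                self.total,
                ", ".join(f"{k}={v}" for k, v in sorted(self.counts.items())),
            )


@dataclass
class PolarizedSiteTable:
    """Per-scaffold table of polarized sites, sorted by position.

    ``pos`` is a 1-based int array; ``freqs`` an (n, 4) float array of
    (p1, p2, p3, p4).  ``callable_pos`` (alignment input only) lists every
    retained aligned position — variant or not — and provides the d_xy
    divisor when available.
    """

    scaffold: str
    scaffold_length: int
    pos: np.ndarray
    freqs: np.ndarray
    callable_pos: Optional[np.ndarray] = None
    drops: DropCounts = field(default_factory=DropCounts)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float).reshape(-1, 4)
        if self.pos.shape[0] != self.freqs.shape[0]:
            raise ValueError("pos and freqs length mismatch")
        self.validate()

    def validate(self) -> None:
        if self.n_sites:
            if np.any(np.diff(self.pos) <= 0):
                raise InputError(
                    f"{self.scaffold}: site positions not strictly increasing"
                )
            if self.pos[-1] > self.scaffold_length:
                raise InputError(
                    f"{self.scaffold}: site position {int(self.pos[-1])} exceeds "
                    f"scaffold length {self.scaffold_length}"
                )
            if np.any(self.freqs < 0) or np.any(self.freqs > 1):
                raise InputError(f"{self.scaffold}: frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def sites(self) -> list[PolarizedSite]:
        return list(self)

    def __iter__(self) -> Iterator[PolarizedSite]:
        for i in range(self.n_sites):
            yield PolarizedSite(
                self.scaffold, int(self.pos[i]), *map(float, self.freqs[i])
            )

    def __len__(self) -> int:
        return self.n_sites


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF

def _sample_freq(gt: tuple, derived_idx: int) -> Optional[float]:
    """Derived-allele dosage / ploidy from a GT tuple; None if any call missing."""
    alleles = [a for a in gt if a is not None]
    if len(alleles) != len(gt) or not alleles:
        return None
    return sum(1 for a in alleles if a == derived_idx) / len(alleles)


def read_vcf(
    path,
    quartet: QuartetConfig,
    permissive_outgroup: bool = False,
) -> list[PolarizedSiteTable]:
    """Read a VCF and return one polarized table per scaffold present.

    Only SNP records are used.  A record is retained when the four mapped
    samples jointly carry exactly two alleles and the outgroup is fixed for
    one of them (``permissive_outgroup`` instead keeps outgroup-polymorphic
    sites, polarizing on the outgroup's majority allele with fractional p4).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    samples = quartet.samples
    for s in samples:
        if s not in sample_names:
            raise ConfigurationError(
                f"sample {s!r} not found in VCF (has: {sample_names})"
            )

    contig_lengths = {
        name: (ctg.length or 0) for name, ctg in vf.header.contigs.items()
    }
    per_scaffold: dict[str, tuple[list, list]] = {}
    drops = DropCounts()
    last_pos: dict[str, int] = {}
    n_records = 0

    for rec in vf:
        n_records += 1
        if rec.chrom in last_pos and rec.pos < last_pos[rec.chrom]:
            raise InputError(f"VCF not sorted at {rec.chrom}:{rec.pos}")
        last_pos[rec.chrom] = rec.pos
        alleles = rec.alleles
        if alleles is None or any(a is None or len(a) != 1 for a in alleles):
            drops.add("not_snp")
            continue
        gts = []
        missing = False
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                missing = True
                break
            gts.append(gt)
        if missing:
            drops.add("missing_genotype")
            continue
        used = sorted({a for gt in gts for a in gt})
        if len(used) < 2:
            drops.add("monomorphic")
            continue
        if len(used) > 2:
            drops.add("multiallelic")
            continue
        out_gt = gts[3]
        out_alleles = set(out_gt)
        if len(out_alleles) == 1:
            ancestral = out_gt[0]
        elif permissive_outgroup:
            counts = Counter(out_gt)
            (top, n_top), *rest = counts.most_common()
            if rest and rest[0][1] == n_top:
                drops.add("outgroup_ambiguous")
                continue
            ancestral = top
        else:
            drops.add("outgroup_polymorphic")
            continue
        derived = used[0] if used[1] == ancestral else used[1]
        if derived == ancestral:
            drops.add("monomorphic")
            continue
        freqs = [_sample_freq(gt, derived) for gt in gts]
        pos_list, freq_list = per_scaffold.setdefault(rec.chrom, ([], []))
        pos_list.append(rec.pos)
        freq_list.append(freqs)

    if n_records == 0:
        logger.warning("%s: VCF contains no variant records", path)
    drops.log_summary(str(path))

    tables = []
    for scaffold, (pos_list, freq_list) in per_scaffold.items():
        length = contig_lengths.get(scaffold) or (max(pos_list) if pos_list else 0)
        tables.append(
            PolarizedSiteTable(
                scaffold=scaffold,
                scaffold_length=int(length),
                pos=np.array(pos_list),
                freqs=np.array(freq_list, dtype=float),
                drops=drops,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Aligned FASTA

def read_aligned_fasta(
    path, quartet: QuartetConfig, scaffold: Optional[str] = None
) -> PolarizedSiteTable:
    """Polarize a four-record alignment of one scaffold.

    Columns with a gap or ambiguity code in any taxon are skipped, as are
    monomorphic and >2-allele columns.  Coordinates are the 1-based ungapped
    position in the outgroup sequence, so windows are anchored to a single
    reference frame; columns where the outgroup itself is gapped have no
    coordinate and are skipped.  The scaffold name is taken from a
    ``scaffold=NAME`` token in a record description when present, else from
    the file stem, unless given explicitly.
    """
    from Bio import SeqIO

    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 4:
        raise InputError(
            f"{path}: expected exactly 4 aligned records, found {len(records)}"
        )
    by_id = {r.id: r for r in records}
    rows = []
    for sample in quartet.samples:
        if sample not in by_id:
            raise ConfigurationError(
                f"record {sample!r} not found in alignment (has: {sorted(by_id)})"
            )
        rows.append(
            np.frombuffer(str(by_id[sample].seq).upper().encode(), dtype=np.uint8)
        )
    lengths = {row.shape[0] for row in rows}
    if len(lengths) != 1:
        raise InputError(f"{path}: aligned records have unequal lengths {lengths}")
    if scaffold is None:
        for r in records:
            for token in (r.description or "").split():
                if token.startswith("scaffold="):
                    scaffold = token.split("=", 1)[1]
                    break
            if scaffold:
                break
        else:
            scaffold = Path(path).name.removesuffix(".gz").rsplit(".", 1)[0]

    mat = np.vstack(rows)  # (4, L) byte codes in P1,P2,P3,O order
    out_row = mat[3]
    valid_mask = np.ones(mat.shape[1], dtype=bool)
    for code_row in mat:
        valid_mask &= (
            (code_row == ord("A"))
            | (code_row == ord("C"))
            | (code_row == ord("G"))
            | (code_row == ord("T"))
        )
    out_ungapped = out_row != ord("-")
    drops = DropCounts()
    drops.add("gap_or_ambiguous", int(np.count_nonzero(~valid_mask)))
    keep = valid_mask & out_ungapped
    # 1-based ungapped outgroup coordinate of every alignment column
    out_coord = np.cumsum(out_ungapped)
    scaffold_length = int(out_coord[-1]) if out_coord.size else 0

    sub = mat[:, keep]
    coords = out_coord[keep]
    # classify columns: number of distinct bases among the four taxa
    same_as_out = sub == sub[3]
    n_match = same_as_out.sum(axis=0)
    monomorphic = n_match == 4
    # for columns not monomorphic: biallelic iff all non-outgroup bases equal
    diff = np.where(same_as_out, -1, sub.astype(np.int16))
    alt = diff.max(axis=0)
    biallelic = (~monomorphic) & np.all((diff == -1) | (diff == alt), axis=0)
    triallelic = (~monomorphic) & ~biallelic
    drops.add("monomorphic", int(np.count_nonzero(monomorphic)))
    drops.add("triallelic", int(np.count_nonzero(triallelic)))
    freqs = (~same_as_out[:, biallelic]).T.astype(float)
    drops.log_summary(str(path))
    table = PolarizedSiteTable(
        scaffold=scaffold,
        scaffold_length=scaffold_length,
        pos=coords[biallelic],
        freqs=freqs,
        callable_pos=coords,
        drops=drops,
    )
    if table.n_sites == 0:
        logger.warning("%s: alignment yielded no polarized sites", path)
    return table


# ---------------------------------------------------------------------------
# SNP table dialect

def read_snp_table(path, quartet: QuartetConfig) -> list[PolarizedSiteTable]:
    """Read the TSV SNP dialect: header ``scaffold pos <P1> <P2> <P3> <O>``.

    Optional ``#length <scaffold> <bp>`` meta lines supply scaffold lengths;
    without them the last position observed is used.  Polarization contract
    matches :func:`read_vcf`.
    """
    samples = quartet.samples
    drops = DropCounts()
    per_scaffold: dict[str, tuple[list, list]] = {}
    lengths: dict[str, int] = {}
    header_cols = None
    idx = None
    n_rows = 0

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#length"):
                try:
                    _, scaf, bp = line.split()
                    lengths[scaf] = int(bp)
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: bad #length line") from exc
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header_cols is None:
                header_cols = fields
                if header_cols[:2] != ["scaffold", "pos"]:
                    raise InputError(
                        f"{path}:{lineno}: header must start 'scaffold\\tpos'"
                    )
                try:
                    idx = [header_cols.index(s) for s in samples]
                except ValueError as exc:
                    raise ConfigurationError(
                        f"{path}: header {header_cols} lacks a quartet sample"
                    ) from exc
                continue
            if len(fields) != len(header_cols):
                raise InputError(
                    f"{path}:{lineno}: expected {len(header_cols)} fields, "
                    f"got {len(fields)}"
                )
            n_rows += 1
            scaffold = fields[0]
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: bad position {fields[1]!r}") from exc
            bases = [fields[i].upper() for i in idx]
            if any(len(b) != 1 or ord(b) not in _VALID_BASES for b in bases):
                drops.add("gap_or_ambiguous")
                continue
            distinct = set(bases)
            if len(distinct) == 1:
                drops.add("monomorphic")
                continue
            if len(distinct) > 2:
                drops.add("triallelic")
                continue
            ancestral = bases[3]
            freqs = [0.0 if b == ancestral else 1.0 for b in bases]
            pos_list, freq_list = per_scaffold.setdefault(scaffold, ([], []))
            pos_list.append(pos)
            freq_list.append(freqs)

    if header_cols is None:
        raise InputError(f"{path}: empty file (no header)")
    if n_rows == 0:
        logger.warning("%s: SNP table has a header but no rows", path)
    drops.log_summary(str(path))

    tables = []
    for scaffold, (pos_list, freq_list) in per_scaffold.items():
        length = lengths.get(scaffold, max(pos_list) if pos_list else 0)
        tables.append(
            PolarizedSiteTable(
                scaffold=scaffold,
                scaffold_length=int(length),
                pos=np.array(pos_list),
                freqs=np.array(freq_list, dtype=float),
                drops=drops,
            )
        )
    return tables


def write_snp_table(tables: list[PolarizedSiteTable], path, quartet: QuartetConfig):
    """Write haploid tables to the TSV SNP dialect (round-trip exact).

    Frequencies must be in {0, 1}; ancestral states are written as A and
    derived as G (the dialect carries alleles, not frequencies, so only
    haploid tables are representable).
    """
    samples = quartet.samples
    with open(path, "w") as fh:
        for t in tables:
            fh.write(f"#length {t.scaffold} {t.scaffold_length}\n")
        fh.write("scaffold\tpos\t" + "\t".join(samples) + "\n")
        for t in tables:
            if t.n_sites and not np.isin(t.freqs, (0.0, 1.0)).all():
                raise ValueError(
                    f"{t.scaffold}: fractional frequencies are not representable "
                    "in the allele-per-taxon SNP dialect"
                )
            for i in range(t.n_sites):
                alleles = ["G" if f else "A" for f in t.freqs[i]]
                fh.write(f"{t.scaffold}\t{int(t.pos[i])}\t" + "\t".join(alleles) + "\n")
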