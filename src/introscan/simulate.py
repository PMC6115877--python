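"""Four-taxon genome simulator with planted introgression tracts.

The model is deliberately minimal: it reproduces exactly the statistical
structure the window-scan statistics assume, nothing more.

* A species tree ((P1, P2), P3), O with ultrametric split depths ``d12``
  (P1-P2), ``d123`` (P1P2-P3) and ``d_o`` (root-to-tips for the outgroup),
  all in expected substitutions per site, evolved under JC69.
* Incomplete lineage sorting is emulated by block-wise topology resampling:
  the genome is cut into blocks of ``ils_block_length`` bp and each block
  independently draws a discordant ingroup genealogy with probability
  ``ils_prob`` — the two discordant topologies ((P2,P3),P1) and ((P1,P3),P2)
  are equiprobable, so expected ABBA and BABA densities are equal outside
  tracts and genome-wide D is centred on zero (the no-introgression null).
* Introgression is modelled as tract replacement: within each configured
  tract the recipient's sequence is re-derived from the donor's final
  sequence with ``residual_divergence`` substitutions/site.  This creates
  simultaneously the ABBA excess the D/f_d stages detect and the locally
  reduced donor-recipient d_xy the divergence stage requires — the feature
  that distinguishes introgression from lineage sorting.

Outputs (all plain text, mutually consistent): a four-row aligned FASTA per
scaffold, a VCF of biallelic quartet SNPs, a BED6 truth file of the planted
tracts, a synthetic GFF3 of tiled gene models, and a JSON run manifest.
:func:`expected_pattern_rates` gives the exact per-regime ABBA/BABA site
densities under the same JC69 model, for validating the simulator by
Monte Carlo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "Tract",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "default_config",
    "simulate",
    "expected_pattern_rates",
    "read_bed",
]

TAXA = ("P1", "P2", "P3", "O")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-site regime codes
REGIME_CONCORDANT = 0
REGIME_DISCORDANT_23 = 1  # ingroup genealogy ((P2,P3),P1)
REGIME_DISCORDANT_13 = 2  # ingroup genealogy ((P1,P3),P2)
REGIME_TRACT = 3


@dataclass(frozen=True)
class Tract:
    """A planted donor→recipient introgression tract (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    donor: str = "P3"
    recipient: str = "P2"
    residual_divergence: float = 0.01

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad tract interval [{self.start}, {self.end})")
        if self.donor not in TAXA or self.recipient not in TAXA:
            raise ValueError("tract donor/recipient must be one of P1,P2,P3,O")
        if self.donor == self.recipient:
            raise ValueError("tract donor and recipient must differ")
        if self.residual_divergence < 0:
            raise ValueError("residual_divergence must be >= 0")


@dataclass
class SimConfig:
    """Simulation parameters; ``seed`` is mandatory (no global randomness).

    Split depths are ultrametric distances from the tips, so they must be
    ordered d12 <= d123 <= d_o.
    """

    scaffold_lengths: dict = field(default_factory=lambda: {"sc_1": 1_000_000})
    d12: float = 0.02
    d123: float = 0.05
    d_o: float = 0.10
    ils_block_length: int = 100
    ils_prob: float = 0.2
    tracts: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.d12 <= self.d123 <= self.d_o:
            raise ValueError("split depths must satisfy 0 <= d12 <= d123 <= d_o")
        if not 0 <= self.ils_prob <= 1:
            raise ValueError("ils_prob must be in [0, 1]")
        if self.ils_block_length < 1:
            raise ValueError("ils_block_length must be >= 1")
        self.tracts = [t if isinstance(t, Tract) else Tract(**t) for t in self.tracts]
        by_scaffold: dict[str, list[Tract]] = {}
        for t in self.tracts:
            if t.scaffold not in self.scaffold_lengths:
                raise ValueError(f"tract on unknown scaffold {t.scaffold!r}")
            if t.end > self.scaffold_lengths[t.scaffold]:
                raise ValueError(f"tract {t} exceeds scaffold length")
            by_scaffold.setdefault(t.scaffold, []).append(t)
        for tracts in by_scaffold.values():
            tracts = sorted(tracts, key=lambda t: t.start)
            for a, b in zip(tracts, tracts[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping tracts {a} and {b}")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tracts"] = [asdict(t) for t in self.tracts]
        return d


def default_config(seed: int = 1) -> SimConfig:
    """The reference study conditions: one 1 Mb scaffold, moderate lineage
    sorting (20% discordant 100-bp blocks), and ten evenly spaced 5-kb
    P3→P2 tracts with residual divergence 0.01 — one tenth of the 2·d123
    donor-recipient background."""
    tracts = [
        Tract("sc_1", 50_000 + k * 90_000, 55_000 + k * 90_000) for k in range(10)
    ]
    return SimConfig(tracts=tracts, seed=seed)


def null_config(seed: int = 1, genome_length: int = 1_000_000) -> SimConfig:
    """The symmetric no-introgression regime (same parameters, no tracts)."""
    return SimConfig(scaffold_lengths={"sc_1": genome_length}, seed=seed)


@dataclass
class SimTruth:
    """Planted tract coordinates plus realized per-tract SNP counts."""

    tracts: list
    site_counts: list  # biallelic quartet SNPs realized inside each tract


@dataclass
class SimResult:
    config: SimConfig
    seqs: dict  # scaffold -> (4, L) uint8 base-index matrix, rows P1,P2,P3,O
    regimes: dict  # scaffold -> (L,) uint8 per-site regime code
    truth: SimTruth
    files: dict = field(default_factory=dict)  # role -> path (when written)


# ---------------------------------------------------------------------------
# JC69 machinery

def _p_change(d: float) -> float:
    """JC69 probability that a site shows a different base after distance d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a base-index array along a branch of d substitutions/site."""
    if d == 0:
        return seq.copy()
    mask = rng.random(seq.shape[0]) < _p_change(d)
    out = seq.copy()
    # a uniformly chosen *different* base at each mutated site
    out[mask] = (seq[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def _simulate_scaffold(
    length: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return ((4, L) sequence matrix, (L,) regime codes) before tracts."""
    anc = rng.integers(0, 4, size=length, dtype=np.uint8)
    n_blocks = -(-length // cfg.ils_block_length)
    topo_block = rng.choice(
        3, size=n_blocks, p=[1 - cfg.ils_prob, cfg.ils_prob / 2, cfg.ils_prob / 2]
    ).astype(np.uint8)
    regime = np.repeat(topo_block, cfg.ils_block_length)[:length]

    # branches shared by every genealogy
    o_seq = _evolve(anc, cfg.d_o, rng)
    n123 = _evolve(anc, cfg.d_o - cfg.d123, rng)

    t_inner = cfg.d123 - cfg.d12  # internal branch within the ingroup
    leaves = np.empty((3, 3, length), dtype=np.uint8)  # [topology, taxon, site]
    for topo, (sister_a, sister_b, outer) in enumerate(
        [(0, 1, 2), (1, 2, 0), (0, 2, 1)]  # taxon indices P1=0 P2=1 P3=2
    ):
        pair_anc = _evolve(n123, t_inner, rng)
        leaves[topo, sister_a] = _evolve(pair_anc, cfg.d12, rng)
        leaves[topo, sister_b] = _evolve(pair_anc, cfg.d12, rng)
        leaves[topo, outer] = _evolve(n123, cfg.d123, rng)

    seqs = np.empty((4, length), dtype=np.uint8)
    idx = np.arange(length)
    for taxon in range(3):
        seqs[taxon] = leaves[regime, taxon, idx]
    seqs[3] = o_seq
    return seqs, regime


def _apply_tracts(seqs_by_scaffold, regimes, cfg, rng):
    for t in cfg.tracts:
        seqs = seqs_by_scaffold[t.scaffold]
        donor_row = TAXA.index(t.donor)
        rec_row = TAXA.index(t.recipient)
        seqs[rec_row, t.start : t.end] = _evolve(
            seqs[donor_row, t.start : t.end], t.residual_divergence, rng
        )
        regimes[t.scaffold][t.start : t.end] = REGIME_TRACT


def _biallelic_mask(seqs: np.ndarray) -> np.ndarray:
    """Sites where the four taxa carry exactly two distinct bases."""
    distinct = np.ones(seqs.shape[1], dtype=np.int8)
    seen = np.zeros((4, seqs.shape[1]), dtype=bool)
    for row in seqs:
        seen[row, np.arange(seqs.shape[1])] = True
    n_distinct = seen.sum(axis=0)
    return n_distinct == 2


def simulate(config: SimConfig, out_dir=None) -> SimResult:
    """Run the simulation; optionally write FASTA/VCF/BED/GFF/manifest.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    seqs_by_scaffold = {}
    regimes = {}
    for scaffold, length in config.scaffold_lengths.items():
        seqs, regime = _simulate_scaffold(length, config, rng)
        seqs_by_scaffold[scaffold] = seqs
        regimes[scaffold] = regime
    _apply_tracts(seqs_by_scaffold, regimes, config, rng)

    site_counts = []
    for t in config.tracts:
        sub = seqs_by_scaffold[t.scaffold][:, t.start : t.end]
        site_counts.append(int(_biallelic_mask(sub).sum()))
    truth = SimTruth(tracts=list(config.tracts), site_counts=site_counts)

    result = SimResult(
        config=config, seqs=seqs_by_scaffold, regimes=regimes, truth=truth
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


# ---------------------------------------------------------------------------
# Writers

def _write_outputs(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    files = {}

    for scaffold, seqs in result.seqs.items():
        fasta = out_dir / f"alignment_{scaffold}.fasta"
        with open(fasta, "w") as fh:
            for row, taxon in zip(seqs, TAXA):
                fh.write(f">{taxon} scaffold={scaffold} length={row.shape[0]}\n")
                seq = _BASES[row].tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        files[f"fasta:{scaffold}"] = fasta.name

    vcf = out_dir / "variants.vcf"
    _write_vcf(result, vcf)
    files["vcf"] = vcf.name

    bed = out_dir / "truth_tracts.bed"
    with open(bed, "w") as fh:
        for k, (t, n) in enumerate(zip(result.truth.tracts, result.truth.site_counts)):
            fh.write(
                f"{t.scaffold}\t{t.start}\t{t.end}\t"
                f"tract_{k}:{t.donor}>{t.recipient}:sites={n}\t0\t.\n"
            )
    files["truth_bed"] = bed.name

    gff = out_dir / "genes.gff3"
    _write_gff(result, gff)
    files["gff"] = gff.name

    manifest = out_dir / "sim_manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "config": cfg.as_dict(),
                "taxa": list(TAXA),
                "tract_site_counts": result.truth.site_counts,
                "files": files,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    files["manifest"] = manifest.name
    result.files = files


def _write_vcf(result: SimResult, path: Path) -> None:
    """Biallelic quartet SNPs; REF is the outgroup base, haploid GTs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan-simulate\n")
        for scaffold, seqs in result.seqs.items():
            fh.write(f"##contig=<ID={scaffold},length={seqs.shape[1]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(TAXA)
            + "\n"
        )
        for scaffold, seqs in result.seqs.items():
            mask = _biallelic_mask(seqs)
            positions = np.flatnonzero(mask)
            out_row = seqs[3]
            for pos0 in positions:
                col = seqs[:, pos0]
                ref = int(out_row[pos0])
                alt = int(col[col != ref][0])
                gts = "\t".join("0" if b == ref else "1" for b in col)
                fh.write(
                    f"{scaffold}\t{pos0 + 1}\t.\t"
                    f"{chr(_BASES[ref])}\t{chr(_BASES[alt])}\t.\tPASS\t.\tGT\t{gts}\n"
                )


def _write_gff(result: SimResult, path: Path, gene_length: int = 2000,
               spacing: int = 4000) -> None:
    """Synthetic gene models tiled along each scaffold (GFF3, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold, seqs in result.seqs.items():
            length = seqs.shape[1]
            fh.write(f"##sequence-region {scaffold} 1 {length}\n")
            k = 0
            start0 = 1000
            while start0 + gene_length <= length:
                gene_id = f"gene_{scaffold}_{k:04d}"
                strand = "+" if k % 2 == 0 else "-"
                fh.write(
                    f"{scaffold}\tintroscan_sim\tgene\t{start0 + 1}\t"
                    f"{start0 + gene_length}\t.\t{strand}\t.\t"
                    f"ID={gene_id};Name={gene_id};product=synthetic protein {k}\n"
                )
                k += 1
                start0 += spacing


def polarized_tables(result: SimResult) -> list:
    """Build per-scaffold polarized site tables directly from simulated
    sequences (vectorized; equivalent to writing the alignment and calling
    ``variant_io.read_aligned_fasta``, which a test verifies)."""
    from .variant_io import PolarizedSiteTable

    tables = []
    for scaffold, seqs in result.seqs.items():
        length = seqs.shape[1]
        mask = _biallelic_mask(seqs)
        pos = np.flatnonzero(mask) + 1
        freqs = (seqs[:, mask] != seqs[3, mask]).T.astype(float)
        tables.append(
            PolarizedSiteTable(
                scaffold=scaffold,
                scaffold_length=length,
                pos=pos,
                freqs=freqs,
                callable_pos=np.arange(1, length + 1, dtype=np.int64),
            )
        )
    return tables


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED (first four columns): (scaffold, start, end, name) records."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


# ---------------------------------------------------------------------------
# Exact expected pattern rates

def _jc_matrix(d: float) -> np.ndarray:
    e = np.exp(-4.0 * d / 3.0)
    m = np.full((4, 4), 0.25 * (1 - e))
    np.fill_diagonal(m, 0.25 + 0.75 * e)
    return m


def _pattern_probs(branches: dict[str, float], topo: int, tract_r: Optional[float]
                   ) -> np.ndarray:
    """Joint leaf-state distribution P[p1, p2, p3, o] for one genealogy.

    ``topo`` indexes the ingroup topology (0 concordant, 1 ((P2,P3),P1),
    2 ((P1,P3),P2)); ``tract_r`` when set re-derives P2 from the P3 leaf at
    distance r (the tract-replacement model).
    """
    t_o = _jc_matrix(branches["d_o"])
    t_root = _jc_matrix(branches["d_o"] - branches["d123"])
    t_outer = _jc_matrix(branches["d123"])
    t_inner = _jc_matrix(branches["d123"] - branches["d12"])
    t_tip = _jc_matrix(branches["d12"])

    pairings = {0: (0, 1, 2), 1: (1, 2, 0), 2: (0, 2, 1)}
    sa, sb, outer = pairings[topo]
    # P[a (=n123 state), taxon states]: root r0 uniform; O from r0; a from r0
    # joint over (a, o): sum_r0 1/4 T_root[r0,a] T_o[r0,o]
    p_ao = np.einsum("r,ra,ro->ao", np.full(4, 0.25), t_root, t_o)
    # ingroup leaves given a: sisters via pair ancestor b, outer direct
    p_sisters = np.einsum("ab,bx,by->axy", t_inner, t_tip, t_tip)  # [a, sa, sb]
    # P[sa, sb, outer_leaf, o] = sum_a p_ao[a,o] p_sisters[a,sa,sb] t_outer[a,outer]
    full = np.einsum("ao,axy,az->xyzo", p_ao, p_sisters, t_outer)
    # reorder leaf axes from (sister_a, sister_b, outer) to (P1, P2, P3)
    joint = np.moveaxis(full, (0, 1, 2), (sa, sb, outer))
    if tract_r is not None:
        t_r = _jc_matrix(tract_r)
        # replace P2 (axis 1) by a leaf re-derived from the P3 state (axis 2)
        marg = joint.sum(axis=1)  # [p1, p3, o]
        joint = np.einsum("xzo,zy->xyzo", marg, t_r)
    return joint


def _regime_rates(joint: np.ndarray) -> tuple[float, float]:
    """(e_abba, e_baba): probabilities of the two haploid biallelic patterns."""
    e_abba = e_baba = 0.0
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            e_abba += joint[x, y, y, x]
            e_baba += joint[y, x, y, x]
    return float(e_abba), float(e_baba)


def expected_pattern_rates(config: SimConfig) -> dict[str, tuple[float, float]]:
    """Exact per-site (e_abba, e_baba) for each simulation regime.

    Regimes: "concordant", "discordant_23", "discordant_13" (the block
    genealogies outside tracts) and "tract" (the ILS mixture with the
    recipient re-derived from the donor; uses the first tract's residual
    divergence, or the default, and assumes the default P3→P2 direction).
    Outside tracts the two discordant regimes are mirror images, so the
    genome-wide expectation satisfies E[ABBA] = E[BABA].
    """
    branches = {"d12": config.d12, "d123": config.d123, "d_o": config.d_o}
    rates = {}
    for name, topo in [
        ("concordant", 0),
        ("discordant_23", 1),
        ("discordant_13", 2),
    ]:
        rates[name] = _regime_rates(_pattern_probs(branches, topo, None))
    r = config.tracts[0].residual_divergence if config.tracts else 0.01
    w = [1 - config.ils_prob, config.ils_prob / 2, config.ils_prob / 2]
    tract_joint = sum(
        wk * _pattern_probs(branches, topo, r) for topo, wk in enumerate(w)
    )
    rates["tract"] = _regime_rates(tract_joint)
    return rates
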