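"""Forward simulation of a closed studbook with gene-dropped genotypes.

The simulator emulates the demographic structure of a purebred dog
registry: a founding cohort, a period during which parentless entries
(imports) are still admitted, closure of the studbook, a popular-sire
mating skew, and optionally an abrupt census bottleneck. Genotypes are
produced by dropping uniquely labeled founder haplotypes through the
pedigree with Haldane (no-interference) recombination, so the autozygous
tracts of every individual are known exactly — they are the intervals
where both haplotypes descend from the same founder allele.

Two marker panels are emitted per genome: a sparse chip-like panel
(mean spacing ~14 kb) and a dense sequencing-like panel (~300 bp),
both Poisson-spaced with founder allele frequencies drawn per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap
from .pedigree import PedigreeTable, inbreeding, build_reference_pedigree

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulationExtinctError",
    "simulate_pedigree",
    "gene_drop_genotypes",
]


class SimulationExtinctError(RuntimeError):
    """The simulated population died out before end_year."""

    def __init__(self, year: int):
        self.year = year
        super().__init__(f"population extinct in year {year}")


@dataclass
class SimConfig:
    """Demographic and genomic parameters of one simulated breed.

    sire_concentration c maps to the probability c/(1+c) that a litter is
    sired by the current top-prestige male (0 = random mating). The
    bottleneck, if given, is (year, surviving_fraction): in that year each
    living dog survives independently with the given probability.
    Parentless immigrants are admitted each year strictly before
    closure_year, after which the studbook is closed.
    """

    n_founders: int = 30
    start_year: int = 1950
    end_year: int = 2015
    closure_year: int = 1975
    litters_per_year: float = 10.0
    litter_size_mean: float = 4.0
    sire_concentration: float = 1.0
    bottleneck: tuple[int, float] | None = None
    genome: Sequence[tuple[str, int]] = (("1", 30_000_000),)
    sparse_spacing_bp: float = 14_000.0
    dense_spacing_bp: float = 300.0
    immigrants_per_year: int = 2
    recomb_rate_cm_per_mb: float = 1.0
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    max_breeding_age: int = 8
    lifespan: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.sparse_spacing_bp <= 0 or self.dense_spacing_bp <= 0:
            raise ValueError("marker spacings must be positive")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.sire_concentration < 0:
            raise ValueError("sire_concentration must be >= 0")

    @property
    def popular_sire_prob(self) -> float:
        c = self.sire_concentration
        return c / (1.0 + c)


@dataclass
class TruthRecord:
    """Ground truth carried alongside simulated data.

    ``expected_f`` is the pedigree-expected inbreeding coefficient per
    individual. ``tracts`` maps individual id -> list of (chrom, start,
    end) autozygosity intervals (0-based half-open, bp) where the two
    haplotypes descend from the same founder allele; filled by
    :func:`gene_drop_genotypes`. ``haplotypes`` keeps the founder-mosaic
    representation per individual for inspection in tests.
    """

    expected_f: pd.Series
    tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    haplotypes: dict = field(default_factory=dict)

    def tracts_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, start, end, ind)
            for ind, tr in self.tracts.items()
            for chrom, start, end in tr
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "individual"])


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> tuple[PedigreeTable, TruthRecord]:
    """Simulate a closed-registry pedigree; returns the table and truth.

    Deterministic under a fixed ``config.seed``. Raises
    :class:`SimulationExtinctError` if, once the studbook has closed, no
    living dogs of one sex remain before ``end_year``.
    """
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sexes: list[str] = []
    years: list[int] = []
    prestige: list[float] = []
    alive: list[bool] = []

    def add(sire: str, dam: str, sex: str, year: int) -> int:
        k = len(ids)
        ids.append(f"I{k:06d}")
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        years.append(year)
        prestige.append(float(rng.random()))
        alive.append(True)
        return k

    for j in range(config.n_founders):
        add("0", "0", "MF"[j % 2], config.start_year)

    pi = config.popular_sire_prob
    for year in range(config.start_year + 1, config.end_year + 1):
        if year < config.closure_year:
            n_alive = sum(alive)
            for j in range(config.immigrants_per_year):
                add("0", "0", "MF"[(n_alive + j) % 2], year)
        # retire and bury
        for k in range(len(ids)):
            if alive[k] and year - years[k] >= config.lifespan:
                alive[k] = False
        males = [
            k for k in range(len(ids))
            if alive[k] and sexes[k] == "M"
            and 1 <= year - years[k] <= config.max_breeding_age
        ]
        females = [
            k for k in range(len(ids))
            if alive[k] and sexes[k] == "F"
            and 1 <= year - years[k] <= config.max_breeding_age
        ]
        if not males or not females:
            if year >= config.closure_year and (
                not any(alive[k] and sexes[k] == "M" for k in range(len(ids)))
                or not any(alive[k] and sexes[k] == "F" for k in range(len(ids)))
            ):
                raise SimulationExtinctError(year)
            continue
        top_sire = max(males, key=lambda k: prestige[k])
        n_litters = min(int(rng.poisson(config.litters_per_year)), len(females))
        litter_dams = rng.choice(
            np.asarray(females), size=n_litters, replace=False
        )
        for dam_k in litter_dams:
            if pi > 0 and rng.random() < pi:
                sire_k = top_sire
            else:
                sire_k = int(rng.choice(np.asarray(males)))
            for _ in range(int(rng.poisson(config.litter_size_mean))):
                add(ids[sire_k], ids[int(dam_k)], "MF"[int(rng.integers(2))], year)
        if config.bottleneck is not None and year == config.bottleneck[0]:
            frac = config.bottleneck[1]
            for k in range(len(ids)):
                if alive[k] and rng.random() > frac:
                    alive[k] = False
        if year >= config.closure_year and not any(alive):
            raise SimulationExtinctError(year)

    ped = PedigreeTable(
        pd.DataFrame(
            {
                "id": ids,
                "sire": sires,
                "dam": dams,
                "sex": sexes,
                "birth_year": years,
                "region": "SIM",
            }
        )
    )
    refped = build_reference_pedigree(
        ped, (config.start_year, config.end_year)
    )
    expected_f = inbreeding(refped, depth="full").f
    return ped, TruthRecord(expected_f=expected_f)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _poisson_positions(rng, length: int, mean_spacing: float) -> np.ndarray:
    """Poisson-process marker positions with the given mean spacing."""
    out: list[np.ndarray] = []
    total = 0.0
    while total < length:
        gaps = rng.exponential(
            mean_spacing, size=max(4, int(2 * length / mean_spacing))
        )
        pos = total + np.cumsum(gaps)
        total = float(pos[-1])
        out.append(pos)
    pos = np.concatenate(out)
    pos = pos[pos < length].astype(np.int64)
    if len(pos) == 0:
        pos = np.asarray([length // 2], dtype=np.int64)
    return np.unique(pos)


def _recombine(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    length: int,
    rate_per_bp: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: a mosaic of the two parental haplotypes.

    Haplotypes are (breaks, labels): segment i covers
    [breaks[i], breaks[i+1]) with founder-allele label labels[i]; breaks
    start at 0 and end is implicit at chromosome length.
    """
    n_x = rng.poisson(length * rate_per_bp)
    start_with_a = bool(rng.integers(2))
    if n_x == 0:
        src = hap_a if start_with_a else hap_b
        return src[0].copy(), src[1].copy()
    xovers = np.sort(rng.integers(1, length, size=n_x).astype(np.int64))
    bounds = np.concatenate(([0], xovers, [length]))
    out_breaks: list[int] = []
    out_labels: list[int] = []
    use_a = start_with_a
    for s, e in zip(bounds[:-1], bounds[1:]):
        if s == e:
            use_a = not use_a
            continue
        breaks, labels = hap_a if use_a else hap_b
        i = int(np.searchsorted(breaks, s, side="right")) - 1
        pos = s
        while pos < e:
            nxt = breaks[i + 1] if i + 1 < len(breaks) else length
            seg_end = min(int(nxt), e)
            if out_labels and out_labels[-1] == labels[i]:
                pass  # merge with previous segment
            else:
                out_breaks.append(pos)
                out_labels.append(int(labels[i]))
            pos = seg_end
            i += 1
        use_a = not use_a
    return np.asarray(out_breaks, dtype=np.int64), np.asarray(out_labels, dtype=np.int64)


def _autozygous_intervals(
    hap1: tuple[np.ndarray, np.ndarray],
    hap2: tuple[np.ndarray, np.ndarray],
    length: int,
) -> list[tuple[int, int]]:
    """Maximal intervals where both haplotypes carry the same founder label."""
    b1, l1 = hap1
    b2, l2 = hap2
    bounds = np.unique(np.concatenate((b1, b2, [0, length])))
    out: list[tuple[int, int]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if s >= e:
            continue
        lab1 = l1[int(np.searchsorted(b1, s, side="right")) - 1]
        lab2 = l2[int(np.searchsorted(b2, s, side="right")) - 1]
        if lab1 == lab2:
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], int(e))
            else:
                out.append((int(s), int(e)))
    return out


def gene_drop_genotypes(
    ped: PedigreeTable,
    config: SimConfig,
    panels: Sequence[str] = ("sparse", "dense"),
    panel_seed: int | None = None,
) -> tuple[GenotypeMatrix | None, GenotypeMatrix | None, TruthRecord]:
    """Drop founder haplotypes through ``ped``; emit panels and truth.

    Returns (sparse, dense, truth); a panel not requested in ``panels`` is
    returned as None (the IBD truth is always computed). Every founder
    haplotype — including the unknown-parent side of a half-documented
    individual — receives a unique label, so autozygosity truth requires
    no inference. Genotypes are drawn per panel from ancestral allele
    frequencies Uniform(``config.founder_freq_range``) per marker.

    ``panel_seed`` fixes the marker positions and ancestral frequencies
    independently of ``config.seed``: simulating several breeds with the
    same ``panel_seed`` yields genotypes on one common chip-style panel,
    with each breed's founder haplotypes drawn as samples from the same
    ancestral frequency spectrum — the setting a multi-breed genotyping
    study assumes.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x9E3779B9]).generate_state(1)[0]
    )
    panel_rng_seed = config.seed if panel_seed is None else panel_seed
    sire_idx, dam_idx = ped.parent_indices()
    topo = ped.topological_order()
    n = len(ped)
    rate_per_bp = config.recomb_rate_cm_per_mb * 1e-8

    # unique founder-haplotype labels per unknown-parent side
    n_labels = 0
    side_label = np.full((n, 2), -1, dtype=np.int64)
    for k in range(n):
        for s, p in enumerate((sire_idx[k], dam_idx[k])):
            if p < 0:
                side_label[k, s] = n_labels
                n_labels += 1

    haplotypes: dict[str, dict[str, list]] = {i: {} for i in ped.ids}
    tracts: dict[str, list[tuple[str, int, int]]] = {i: [] for i in ped.ids}
    hap_store: list[dict] = [dict() for _ in range(n)]  # chrom -> [hap0, hap1]

    for chrom, length in config.genome:
        for k in topo:
            pair = []
            for s, p in enumerate((sire_idx[k], dam_idx[k])):
                if p < 0:
                    lab = side_label[k, s]
                    pair.append(
                        (np.asarray([0], dtype=np.int64),
                         np.asarray([lab], dtype=np.int64))
                    )
                else:
                    parent_pair = hap_store[p][chrom]
                    pair.append(
                        _recombine(parent_pair[0], parent_pair[1],
                                   length, rate_per_bp, rng)
                    )
            hap_store[k][chrom] = pair
        for k in range(n):
            ind = ped.ids[k]
            pair = hap_store[k][chrom]
            haplotypes[ind][chrom] = pair
            for s, e in _autozygous_intervals(pair[0], pair[1], length):
                tracts[ind].append((chrom, s, e))

    sparse = dense = None
    if "sparse" in panels:
        sparse = _extract_panel(
            ped, hap_store, config, rng, config.sparse_spacing_bp, n_labels,
            np.random.default_rng(
                np.random.SeedSequence([panel_rng_seed, 1]).generate_state(1)[0]),
        )
    if "dense" in panels:
        dense = _extract_panel(
            ped, hap_store, config, rng, config.dense_spacing_bp, n_labels,
            np.random.default_rng(
                np.random.SeedSequence([panel_rng_seed, 2]).generate_state(1)[0]),
        )

    refped = build_reference_pedigree(
        ped, (int(ped.df["birth_year"].min()), int(ped.df["birth_year"].max()))
    )
    expected_f = inbreeding(refped, depth="full").f
    truth = TruthRecord(
        expected_f=expected_f, tracts=tracts, haplotypes=haplotypes
    )
    return sparse, dense, truth


def _extract_panel(
    ped: PedigreeTable,
    hap_store: list[dict],
    config: SimConfig,
    rng,
    spacing: float,
    n_labels: int,
    panel_rng,
) -> GenotypeMatrix:
    # marker positions and ancestral frequencies come from the panel
    # stream (shareable across breeds); founder haplotype draws come from
    # the per-breed genotype stream
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom, length in config.genome:
        pos = _poisson_positions(panel_rng, length, spacing)
        chroms.append(chrom)
        positions.append(pos)
    m_total = int(sum(len(p) for p in positions))
    lo, hi = config.founder_freq_range
    freqs = panel_rng.uniform(lo, hi, size=m_total)
    founder_alleles = (
        rng.random((n_labels, m_total)) < freqs[None, :]
    ).astype(np.int8)

    n = len(ped)
    calls = np.empty((n, m_total), dtype=np.int8)
    col0 = 0
    for chrom, pos in zip(chroms, positions):
        m = len(pos)
        for k in range(n):
            pair = hap_store[k][chrom]
            g = np.zeros(m, dtype=np.int8)
            cols = np.arange(col0, col0 + m)
            for breaks, labels in pair:
                seg = np.searchsorted(breaks, pos, side="right") - 1
                g += founder_alleles[labels[seg], cols]
            calls[k, col0:col0 + m] = g
        col0 += m

    rows = []
    j = 0
    for chrom, pos in zip(chroms, positions):
        for p in pos:
            rows.append((chrom, int(p), f"m{j}"))
            j += 1
    marker_map = MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id"]))
    return GenotypeMatrix(samples=ped.ids, calls=calls, markers=marker_map)
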