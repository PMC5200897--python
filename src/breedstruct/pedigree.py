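"""Pedigree-based demography metrics for closed breed populations.

The substrate is a :class:`PedigreeTable` (id, sire, dam, sex, birth_year,
region). On top of it this module computes the classical gene-origin and
inbreeding statistics used to describe a closed studbook:

* pedigree completeness and equivalent complete generations (g_e),
* inbreeding coefficients F by the additive-relationship (tabular)
  recursion, at full or truncated ancestral depth,
* effective population size Ne from the per-generation rate of inbreeding,
* effective numbers of founders, ancestors and founder genomes.

Because real studbooks are often missing parentage at points well after
breed formation, any individual with no recorded parents is treated as an
"earliest documented relative" (EDR) rather than a true founder; an
individual with exactly one unknown parent contributes that unknown side
as a distinct EDR.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "0"

__all__ = [
    "PedigreeTable",
    "ReferencePedigree",
    "InbreedingSeries",
    "ContributionSet",
    "CompletenessReport",
    "NeResult",
    "PedigreeError",
    "validate_pedigree",
    "impute_birth_years",
    "build_reference_pedigree",
    "completeness",
    "inbreeding",
    "effective_population_size",
    "ne_from_reference",
    "edr_effective",
    "edr_ancestors",
    "edr_genomes",
    "bottleneck_ratio",
    "kinship",
    "inbreeding_coefficient",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicate ids, cycles...)."""


@dataclass
class PedigreeTable:
    """A parent map with birth metadata.

    ``df`` holds columns id, sire, dam, sex, birth_year, region. Unknown
    parents are encoded as ``"0"``; unknown sex as ``"U"``; missing birth
    years as NaN. Integer index arrays (``sire_idx``/``dam_idx``, -1 for
    unknown) and a parents-before-children topological order are built
    lazily and cached.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (
            ("sire", UNKNOWN),
            ("dam", UNKNOWN),
            ("sex", "U"),
            ("birth_year", np.nan),
            ("region", ""),
        ):
            if col not in df.columns:
                df[col] = default
        df["id"] = df["id"].astype(str)
        df["sire"] = df["sire"].fillna(UNKNOWN).astype(str)
        df["dam"] = df["dam"].fillna(UNKNOWN).astype(str)
        df.loc[df["sire"].isin(("", "nan")), "sire"] = UNKNOWN
        df.loc[df["dam"].isin(("", "nan")), "dam"] = UNKNOWN
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate id(s): {sorted(set(dup))}")
        self.df = df.reset_index(drop=True)
        self._index = {i: k for k, i in enumerate(self.df["id"])}
        self._cache: dict = {}

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def __len__(self) -> int:
        return len(self.df)

    def index_of(self, ind: str) -> int:
        try:
            return self._index[str(ind)]
        except KeyError:
            raise PedigreeError(f"unknown individual id: {ind!r}") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) integer arrays, -1 for unknown parents."""
        if "pidx" not in self._cache:
            def resolve(col: str) -> np.ndarray:
                out = np.full(len(self.df), -1, dtype=np.int64)
                for k, p in enumerate(self.df[col]):
                    if p != UNKNOWN:
                        if p not in self._index:
                            raise PedigreeError(
                                f"parent {p!r} of {self.df['id'][k]!r} "
                                "is not in the pedigree"
                            )
                        out[k] = self._index[p]
                return out

            self._cache["pidx"] = (resolve("sire"), resolve("dam"))
        return self._cache["pidx"]

    def topological_order(self) -> np.ndarray:
        """Indices ordered so every parent precedes all of its offspring.

        Raises :class:`PedigreeError` if the parent relation is cyclic.
        """
        if "topo" not in self._cache:
            sire, dam = self.parent_indices()
            n = len(self.df)
            n_unresolved = (sire >= 0).astype(np.int64) + (dam >= 0)
            children: list[list[int]] = [[] for _ in range(n)]
            for k in range(n):
                if sire[k] >= 0:
                    children[sire[k]].append(k)
                if dam[k] >= 0:
                    children[dam[k]].append(k)
            order: list[int] = [k for k in range(n) if n_unresolved[k] == 0]
            head = 0
            while head < len(order):
                k = order[head]
                head += 1
                for c in children[k]:
                    n_unresolved[c] -= 1
                    if n_unresolved[c] == 0:
                        order.append(c)
            if len(order) != n:
                cyclic = sorted(
                    self.df["id"][k] for k in range(n) if n_unresolved[k] > 0
                )
                raise PedigreeError(f"pedigree contains a cycle involving {cyclic}")
            self._cache["topo"] = np.asarray(order, dtype=np.int64)
        return self._cache["topo"]

    def subset(self, ids: Iterable[str]) -> "PedigreeTable":
        keep = set(str(i) for i in ids)
        sub = self.df[self.df["id"].isin(keep)].copy()
        sub.loc[~sub["sire"].isin(keep), "sire"] = UNKNOWN
        sub.loc[~sub["dam"].isin(keep), "dam"] = UNKNOWN
        return PedigreeTable(sub)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.df[["id", "sire", "dam", "sex", "birth_year", "region"]].copy()
        out["birth_year"] = out["birth_year"].map(
            lambda y: "" if pd.isna(y) else str(int(y))
        )
        out.to_csv(path, index=False)


@dataclass
class ReferencePedigree:
    """Reference population (a birth-year window) plus its ancestor closure."""

    ped: PedigreeTable          # restricted to the closure
    reference_ids: list[str]
    window: tuple[int, int]

    @property
    def closure_ids(self) -> list[str]:
        return self.ped.ids


@dataclass
class CompletenessReport:
    proportions: np.ndarray     # proportion of known ancestors per generation
    g_e: float                  # equivalent complete generations


@dataclass
class InbreedingSeries:
    f: pd.Series                # per-individual F over the closure, id-indexed
    depth: str                  # "full", "10", "5"
    yearly_mean: pd.Series      # mean F by birth year
    f_reference_mean: float     # mean F of the reference cohort
    f_parent_mean: float        # mean F of their parents


@dataclass
class NeResult:
    delta_f: float | None
    ne: float | None
    defined: bool
    reason: str = ""


@dataclass
class ContributionSet:
    p_i: pd.Series              # proportional EDR contributions, sum 1
    edr_e: float
    p_k: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    edr_a: float | None = None
    top_ancestors: list[tuple[str, float]] = field(default_factory=list)
    r_i: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    edr_g: float | None = None


# ---------------------------------------------------------------------------
# validation and birth-year imputation
# ---------------------------------------------------------------------------

def validate_pedigree(ped: PedigreeTable) -> list[dict]:
    """Flag structurally improbable records.

    Returns one dict per flagged record with keys ``id`` and ``problem``.
    Checks: self-parentage, cycles, sex-inconsistent parentage, and a child
    born before its parent. Duplicate ids raise at table construction.
    """
    flags: list[dict] = []
    df = ped.df
    sex = dict(zip(df["id"], df["sex"]))
    year = dict(zip(df["id"], df["birth_year"]))
    for _, row in df.iterrows():
        if row["sire"] == row["id"] or row["dam"] == row["id"]:
            flags.append({"id": row["id"], "problem": "own parent"})
        for role, want in (("sire", "M"), ("dam", "F")):
            p = row[role]
            if p == UNKNOWN or p not in sex:
                continue
            if sex[p] not in (want, "U"):
                flags.append(
                    {"id": row["id"], "problem": f"{role} {p} has sex {sex[p]}"}
                )
            py, cy = year.get(p), row["birth_year"]
            if not (pd.isna(py) or pd.isna(cy)) and cy < py:
                flags.append(
                    {"id": row["id"],
                     "problem": f"born {int(cy)} before {role} {p} ({int(py)})"}
                )
    try:
        ped.topological_order()
    except PedigreeError:
        # every member of a cycle is flagged
        flags.extend(_cycle_members(ped))
    return flags


def _cycle_members(ped: PedigreeTable) -> list[dict]:
    sire, dam = ped.parent_indices()
    n = len(ped)
    n_unresolved = (sire >= 0).astype(np.int64) + (dam >= 0)
    children: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        for p in (sire[k], dam[k]):
            if p >= 0:
                children[p].append(k)
    queue = [k for k in range(n) if n_unresolved[k] == 0]
    while queue:
        k = queue.pop()
        for c in children[k]:
            n_unresolved[c] -= 1
            if n_unresolved[c] == 0:
                queue.append(c)
    return [
        {"id": ped.df["id"][k], "problem": "part of an ancestry cycle"}
        for k in range(n)
        if n_unresolved[k] > 0
    ]


def impute_birth_years(
    ped: PedigreeTable, generation_interval: int = 2
) -> tuple[PedigreeTable, list[str]]:
    """Fill missing birth years from relatives.

    Priority per the studbook-curation convention: copy from a full
    sibling; else parent year + interval; else offspring year − interval.
    The standard generation interval for imputation is 2 years. Returns
    the completed table and the ids whose year was imputed. Individuals
    with no dated relative are left untouched. One pass is iterated until
    no further year can be filled, so chains of relatives resolve.
    """
    df = ped.df.copy()
    imputed: list[str] = []
    changed = True
    while changed:
        changed = False
        year = dict(zip(df["id"], df["birth_year"]))
        sibs: dict[tuple[str, str], list[str]] = {}
        offspring: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            if row["sire"] != UNKNOWN and row["dam"] != UNKNOWN:
                sibs.setdefault((row["sire"], row["dam"]), []).append(row["id"])
            for p in (row["sire"], row["dam"]):
                if p != UNKNOWN:
                    offspring.setdefault(p, []).append(row["id"])
        for k, row in df.iterrows():
            if not pd.isna(row["birth_year"]):
                continue
            new_year = np.nan
            if row["sire"] != UNKNOWN and row["dam"] != UNKNOWN:
                mates = [
                    year[s]
                    for s in sibs[(row["sire"], row["dam"])]
                    if s != row["id"] and not pd.isna(year[s])
                ]
                if mates:
                    new_year = float(np.min(mates))
            if pd.isna(new_year):
                parents = [
                    year[p]
                    for p in (row["sire"], row["dam"])
                    if p != UNKNOWN and p in year and not pd.isna(year[p])
                ]
                if parents:
                    new_year = float(np.max(parents)) + generation_interval
            if pd.isna(new_year):
                kids = [
                    year[c]
                    for c in offspring.get(row["id"], [])
                    if not pd.isna(year[c])
                ]
                if kids:
                    new_year = float(np.min(kids)) - generation_interval
            if not pd.isna(new_year):
                df.loc[k, "birth_year"] = new_year
                imputed.append(row["id"])
                changed = True
    return PedigreeTable(df), imputed


# ---------------------------------------------------------------------------
# reference pedigree
# ---------------------------------------------------------------------------

def build_reference_pedigree(
    ped: PedigreeTable, window: tuple[int, int]
) -> ReferencePedigree:
    """Individuals born inside ``window`` plus their full ancestor closure.

    Database members that are not reference individuals and not ancestors
    of one are dropped: they do not contribute to the modern population.
    """
    start, end = window
    years = ped.df["birth_year"]
    in_window = ped.df["id"][(years >= start) & (years <= end)]
    reference_ids = list(in_window)
    if not reference_ids:
        raise PedigreeError(f"no individual born in window {start}-{end}")
    sire, dam = ped.parent_indices()
    keep: set[int] = set()
    stack = [ped.index_of(i) for i in reference_ids]
    while stack:
        k = stack.pop()
        if k in keep:
            continue
        keep.add(k)
        for p in (sire[k], dam[k]):
            if p >= 0 and p not in keep:
                stack.append(p)
    closure_ids = [ped.df["id"][k] for k in sorted(keep)]
    return ReferencePedigree(
        ped=ped.subset(closure_ids), reference_ids=reference_ids, window=window
    )


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------

def completeness(
    refped: ReferencePedigree, max_generations: int = 30
) -> CompletenessReport:
    """Per-generation proportion of known ancestors and g_e.

    At generation g there are 2^g ancestor *slots* along the paths from an
    individual; the proportion counts filled slots, averaged over the
    reference population. g_e is the sum of proportions over generations.
    """
    ped = refped.ped
    sire, dam = ped.parent_indices()
    memo: dict[tuple[int, int], int] = {}

    def known_slots(k: int, g: int) -> int:
        if g == 0:
            return 1
        key = (k, g)
        if key not in memo:
            total = 0
            for p in (sire[k], dam[k]):
                if p >= 0:
                    total += known_slots(p, g - 1)
            memo[key] = total
        return memo[key]

    ref_idx = [ped.index_of(i) for i in refped.reference_ids]
    props = np.zeros(max_generations)
    for g in range(1, max_generations + 1):
        props[g - 1] = float(
            np.mean([known_slots(k, g) for k in ref_idx]) / 2.0**g
        )
    return CompletenessReport(proportions=props, g_e=float(props.sum()))


# ---------------------------------------------------------------------------
# kinship / inbreeding (tabular recursion)
# ---------------------------------------------------------------------------

class _Kinship:
    """Memoized additive-relationship kinship over integer parent arrays."""

    def __init__(self, sire: np.ndarray, dam: np.ndarray, rank: np.ndarray):
        self.sire = sire
        self.dam = dam
        self.rank = rank  # topological rank: parents rank lower
        self.memo: dict[tuple[int, int], float] = {}

    def __call__(self, a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a == b:
            key = (a, a)
            if key not in self.memo:
                self.memo[key] = 0.5 * (1.0 + self(self.sire[a], self.dam[a]))
            return self.memo[key]
        if self.rank[a] > self.rank[b]:
            a, b = b, a
        key = (a, b)
        if key not in self.memo:
            self.memo[key] = 0.5 * (
                self(a, self.sire[b]) + self(a, self.dam[b])
            )
        return self.memo[key]

    def inbreeding(self, k: int) -> float:
        return self(self.sire[k], self.dam[k])


def _kinship_engine(ped: PedigreeTable) -> _Kinship:
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    rank = np.empty(len(ped), dtype=np.int64)
    rank[topo] = np.arange(len(ped))
    return _Kinship(sire, dam, rank)


def kinship(ped: PedigreeTable, a: str, b: str) -> float:
    """Coefficient of kinship between two pedigree members."""
    eng = _kinship_engine(ped)
    with _deep_recursion():
        return eng(ped.index_of(a), ped.index_of(b))


def inbreeding_coefficient(ped: PedigreeTable, ind: str) -> float:
    """F of one individual: the kinship of its parents."""
    eng = _kinship_engine(ped)
    with _deep_recursion():
        return eng.inbreeding(ped.index_of(ind))


class _deep_recursion:
    """Temporarily raise the recursion limit for deep pedigrees."""

    def __enter__(self):
        self.old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(self.old, 100_000))

    def __exit__(self, *exc):
        sys.setrecursionlimit(self.old)


def _truncated_parents(
    sire: np.ndarray, dam: np.ndarray, start: int, depth: int
) -> tuple[np.ndarray, np.ndarray]:
    """Parent arrays with ancestors first reached beyond ``depth`` cut.

    Generation distance is the minimum path length from ``start``; an
    ancestor whose minimum generation exceeds ``depth`` becomes unknown.
    """
    min_gen = {start: 0}
    frontier = [start]
    g = 0
    while frontier and g < depth:
        g += 1
        nxt = []
        for k in frontier:
            for p in (sire[k], dam[k]):
                if p >= 0 and p not in min_gen:
                    min_gen[p] = g
                    nxt.append(p)
        frontier = nxt
    ts = sire.copy()
    td = dam.copy()
    for k in min_gen:
        for arr in (ts, td):
            if arr[k] >= 0 and arr[k] not in min_gen:
                arr[k] = -1
    return ts, td


def inbreeding(
    refped: ReferencePedigree, depth: str | int = "full"
) -> InbreedingSeries:
    """Per-individual F over the reference pedigree at a given depth.

    ``depth`` is "full" or a generation count (5 or 10 in the chip-era
    convention): with a finite depth, ancestors first reached beyond that
    many generations are treated as unknown, so F can only decrease.
    Yearly means are taken over all closure members born in each year.
    """
    ped = refped.ped
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    rank = np.empty(len(ped), dtype=np.int64)
    rank[topo] = np.arange(len(ped))
    n = len(ped)
    f = np.zeros(n)
    with _deep_recursion():
        if depth in ("full", None):
            eng = _Kinship(sire, dam, rank)
            for k in range(n):
                f[k] = eng.inbreeding(k)
        else:
            d = int(depth)
            for k in range(n):
                ts, td = _truncated_parents(sire, dam, k, d)
                f[k] = _Kinship(ts, td, rank).inbreeding(k)
    fser = pd.Series(f, index=ped.ids, name="F")
    years = pd.Series(ped.df["birth_year"].values, index=ped.ids)
    yearly = fser.groupby(years).mean()

    ref_idx = [ped.index_of(i) for i in refped.reference_ids]
    parents = {
        int(p)
        for k in ref_idx
        for p in (sire[k], dam[k])
        if p >= 0
    }
    f_ref = float(np.mean(f[ref_idx]))
    f_par = float(np.mean(f[sorted(parents)])) if parents else 0.0
    return InbreedingSeries(
        f=fser,
        depth=str(depth),
        yearly_mean=yearly,
        f_reference_mean=f_ref,
        f_parent_mean=f_par,
    )


# ---------------------------------------------------------------------------
# effective population size
# ---------------------------------------------------------------------------

def effective_population_size(f_ref: float, f_par: float) -> NeResult:
    """Ne from the per-generation rate of inbreeding.

    ΔF = (F_ref − F_par)/(1 − F_par);  Ne = 1/(2 ΔF).
    A non-increasing mean inbreeding gives an explicitly undefined result.
    """
    if not (0 <= f_ref <= 1 and 0 <= f_par < 1):
        raise ValueError("F values must lie in [0, 1) for the parents")
    delta_f = (f_ref - f_par) / (1.0 - f_par)
    if delta_f <= 0:
        return NeResult(
            delta_f=delta_f,
            ne=None,
            defined=False,
            reason="undefined (non-increasing inbreeding)",
        )
    return NeResult(delta_f=delta_f, ne=1.0 / (2.0 * delta_f), defined=True)


def ne_from_reference(series: InbreedingSeries) -> NeResult:
    """Convenience: Ne from the reference-cohort and parent mean F."""
    return effective_population_size(
        series.f_reference_mean, series.f_parent_mean
    )


# ---------------------------------------------------------------------------
# gene-origin statistics: EDR_e, EDR_a, EDR_g
# ---------------------------------------------------------------------------

def _edr_flow(refped: ReferencePedigree) -> tuple[pd.Series, np.ndarray]:
    """Expected proportional contribution of each EDR entity.

    A gene sampled from a random reference individual is traced up the
    pedigree, choosing a parent fair-coin at each step; it terminates at an
    unknown-parent side, attributed to the individual carrying that side
    (a full EDR when both parents are unknown). Returns the terminal
    weights (sum 1) and the per-individual child-inflow used by EDR_a.
    """
    ped = refped.ped
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    n = len(ped)
    init = np.zeros(n)
    for i in refped.reference_ids:
        init[ped.index_of(i)] += 1.0 / len(refped.reference_ids)
    w_children = np.zeros(n)
    terminal = np.zeros(n)
    for k in topo[::-1]:
        total = w_children[k] + init[k]
        if total == 0:
            continue
        for p in (sire[k], dam[k]):
            if p >= 0:
                w_children[p] += total / 2.0
            else:
                terminal[k] += total / 2.0
    p_i = pd.Series(terminal, index=ped.ids)
    p_i = p_i[p_i > 0]
    return p_i, w_children


def edr_effective(refped: ReferencePedigree) -> ContributionSet:
    """Effective number of earliest documented relatives, 1/Σp_i²."""
    if not refped.reference_ids:
        raise PedigreeError("empty reference population")
    p_i, _ = _edr_flow(refped)
    edr_e = 1.0 / float((p_i**2).sum())
    return ContributionSet(p_i=p_i.sort_values(ascending=False), edr_e=edr_e)


def edr_ancestors(
    refped: ReferencePedigree,
    residual_tol: float = 1e-6,
    max_ancestors: int | None = None,
) -> ContributionSet:
    """Effective number of ancestors by greedy marginal contributions.

    Each round selects the ancestor explaining the largest share of the
    reference genome not yet explained by previously selected ancestors
    (Boichard's marginal contribution), until the unexplained residual
    falls below ``residual_tol`` or the pool is exhausted. Ties are broken
    by earliest birth year, then id. EDR_a = 1/Σp_k².
    """
    if not refped.reference_ids:
        raise PedigreeError("empty reference population")
    ped = refped.ped
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    n = len(ped)
    n_unknown = ((sire < 0).astype(float) + (dam < 0)) / 2.0
    init = np.zeros(n)
    for i in refped.reference_ids:
        init[ped.index_of(i)] += 1.0 / len(refped.reference_ids)
    years = ped.df["birth_year"].to_numpy(dtype=float)
    ids = np.asarray(ped.ids)

    selected: list[int] = []
    in_s = np.zeros(n, dtype=bool)
    p_k: list[float] = []
    explained = 0.0
    limit = max_ancestors if max_ancestors is not None else n
    while explained < 1.0 - residual_tol and len(selected) < limit:
        # upward flow with absorption at selected ancestors
        w_children = np.zeros(n)
        for k in topo[::-1]:
            if in_s[k]:
                flow = init[k]       # own genome still traces upward
            else:
                flow = w_children[k] + init[k]
            if flow == 0:
                continue
            for p in (sire[k], dam[k]):
                if p >= 0:
                    w_children[p] += flow / 2.0
        # P(an individual's own gene is explained by the selected set)
        g = np.zeros(n)
        for k in topo:
            acc = 0.0
            for p in (sire[k], dam[k]):
                if p >= 0:
                    acc += 0.5 * (1.0 if in_s[p] else g[p])
            g[k] = acc
        score = w_children * (1.0 - g) + init * n_unknown
        score[in_s] = -1.0
        best = float(score.max())
        if best <= residual_tol * 1e-3:
            break
        tie = np.flatnonzero(score >= best - 1e-15)
        yk = years[tie]
        yk = np.where(np.isnan(yk), np.inf, yk)
        tie = tie[np.lexsort((ids[tie], yk))]
        choice = int(tie[0])
        selected.append(choice)
        in_s[choice] = True
        p_k.append(best)
        explained += best

    pk = pd.Series(p_k, index=[ped.ids[k] for k in selected])
    edr_a = 1.0 / float((pk**2).sum())
    base = edr_effective(refped)
    top = list(pk.iloc[:100].items())
    return ContributionSet(
        p_i=base.p_i,
        edr_e=base.edr_e,
        p_k=pk,
        edr_a=edr_a,
        top_ancestors=top,
    )


def edr_genomes(
    refped: ReferencePedigree, reps: int = 1000, seed: int | None = None
) -> ContributionSet:
    """Founder-genome equivalents by Monte-Carlo gene dropping.

    One unlinked locus is dropped ``reps`` times: each EDR side carries
    uniquely labeled alleles, transmission is a fair coin per meiosis, and
    r_i is the mean fraction of EDR i's alleles surviving in the reference
    population. EDR_g = 1/Σ(p_i²/r_i).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ped = refped.ped
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    n = len(ped)
    rng = np.random.default_rng(seed)

    # allele label per (individual, side); unknown sides get unique labels
    labels = np.full((n, 2), -1, dtype=np.int64)
    owner: list[int] = []       # entity (individual index) owning each label
    for k in range(n):
        for s, p in enumerate((sire[k], dam[k])):
            if p < 0:
                labels[k, s] = len(owner)
                owner.append(k)
    n_alleles = len(owner)
    owner_arr = np.asarray(owner)

    alle = np.empty((n, 2, reps), dtype=np.int64)
    cols = np.arange(reps)
    for k in topo:
        for s, p in enumerate((sire[k], dam[k])):
            if p < 0:
                alle[k, s, :] = labels[k, s]
            else:
                pick = rng.integers(0, 2, size=reps)
                alle[k, s, :] = alle[p, pick, cols]

    ref_idx = np.asarray([ped.index_of(i) for i in refped.reference_ids])
    surviving = np.zeros((n_alleles, reps), dtype=bool)
    flat = alle[ref_idx].reshape(-1, reps)
    for r in range(reps):
        surviving[np.unique(flat[:, r]), r] = True

    per_entity = np.zeros(n)
    entity_alleles = np.zeros(n)
    for a in range(n_alleles):
        entity_alleles[owner_arr[a]] += 1
    surv_count = surviving.mean(axis=1)      # per-allele survival prob
    for a in range(n_alleles):
        per_entity[owner_arr[a]] += surv_count[a]
    with np.errstate(invalid="ignore", divide="ignore"):
        r_full = per_entity / entity_alleles
    base = edr_effective(refped)
    r_i = pd.Series(
        [r_full[ped.index_of(i)] for i in base.p_i.index], index=base.p_i.index
    )
    floor = 1.0 / (2.0 * reps)
    r_i = r_i.clip(lower=floor)
    edr_g = 1.0 / float((base.p_i**2 / r_i).sum())
    return ContributionSet(p_i=base.p_i, edr_e=base.edr_e, r_i=r_i, edr_g=edr_g)


def bottleneck_ratio(c: ContributionSet) -> float:
    """EDR_e / EDR_a; values above one indicate a historical bottleneck."""
    if c.edr_a is None:
        raise ValueError("EDR_a has not been computed on this ContributionSet")
    return c.edr_e / c.edr_a
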