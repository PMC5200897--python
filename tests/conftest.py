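"""Shared fixtures: toy pedigrees, independent oracles, simulated bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import breedstruct as bs
from breedstruct.pedigree import PedigreeTable


def make_ped(rows) -> PedigreeTable:
    """rows: (id, sire, dam, sex, birth_year) tuples; '0' = unknown."""
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year"])
    return PedigreeTable(df)


@pytest.fixture
def fullsib_ped():
    return make_ped([
        ("A", "0", "0", "M", 2000),
        ("B", "0", "0", "F", 2000),
        ("C", "A", "B", "M", 2001),
        ("D", "A", "B", "F", 2001),
        ("E", "C", "D", "M", 2002),
    ])


@pytest.fixture
def halfsib_ped():
    return make_ped([
        ("A", "0", "0", "M", 2000),
        ("B", "0", "0", "F", 2000),
        ("C", "0", "0", "F", 2000),
        ("D", "A", "B", "M", 2001),
        ("E", "A", "C", "F", 2001),
        ("F", "D", "E", "M", 2002),
    ])


@pytest.fixture
def cousin_ped():
    # G and H are full sibs; their children I and J are first cousins
    return make_ped([
        ("A", "0", "0", "M", 2000),
        ("B", "0", "0", "F", 2000),
        ("C", "0", "0", "F", 2000),
        ("D", "0", "0", "M", 2000),
        ("G", "A", "B", "M", 2001),
        ("H", "A", "B", "F", 2001),
        ("I", "G", "C", "M", 2002),
        ("J", "D", "H", "F", 2002),
        ("K", "I", "J", "M", 2003),
    ])


@pytest.fixture
def deep_common_ancestor_ped():
    """Only common ancestor of X's parents sits 6 generations above X."""
    rows = [("Z", "0", "0", "M", 1900)]
    prev = "Z"
    for g in range(5, 0, -1):              # sire-side chain S5..S1
        rows.append((f"S{g}", prev, "0", "M", 1900 + (6 - g)))
        prev = f"S{g}"
    prev = "Z"
    for g in range(5, 0, -1):              # dam-side chain D5..D1
        rows.append((f"D{g}", prev, "0", "F", 1900 + (6 - g)))
        prev = f"D{g}"
    rows.append(("X", "S1", "D1", "M", 1906))
    return make_ped(rows)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wright_path_f(ped: PedigreeTable, ind: str) -> float:
    """Wright's path-counting inbreeding coefficient (independent oracle).

    F = sum over common ancestors A and over pairs of parent-to-A paths
    sharing no node but A of (1/2)^(n + n' + 1) (1 + F_A).
    """
    sire, dam = ped.parent_indices()

    def paths_up(k):
        """All ancestor paths (node tuples starting at k)."""
        out = [(k,)]
        for p in (sire[k], dam[k]):
            if p >= 0:
                out.extend([(k,) + q for q in paths_up(p)])
        return out

    def f_of(k) -> float:
        s, d = sire[k], dam[k]
        if s < 0 or d < 0:
            return 0.0
        total = 0.0
        for p1 in paths_up(s):
            for p2 in paths_up(d):
                if p1[-1] != p2[-1]:
                    continue
                a = p1[-1]
                if set(p1[:-1]) & set(p2[:-1]):
                    continue
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + f_of(a))
        return total

    return f_of(ped.index_of(ind))


def random_pedigree(rng: np.random.Generator, n: int) -> PedigreeTable:
    """Random acyclic pedigree of n individuals for oracle comparisons."""
    rows = []
    males, females = [], []
    for k in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = "0"
        if males and rng.random() < 0.75:
            sire = males[int(rng.integers(len(males)))]
        if females and rng.random() < 0.75:
            dam = females[int(rng.integers(len(females)))]
        ident = f"R{k:03d}"
        rows.append((ident, sire, dam, sex, 2000 + k))
        (males if sex == "M" else females).append(ident)
    return make_ped(rows)


def brute_force_marginal_contributions(
    refped: bs.ReferencePedigree,
) -> pd.Series:
    """Greedy marginal ancestor contributions by explicit path enumeration.

    Traces every gene path of every reference individual (fair coin per
    meiosis, terminating at unknown-parent sides) and at each round
    selects the candidate explaining the largest probability mass not
    explained by previously selected ancestors, attributing a path to a
    candidate when the candidate is visited as an ancestor or the path
    terminates at the candidate's unknown side. Exponential; toys only.
    """
    ped = refped.ped
    sire, dam = ped.parent_indices()

    paths = []  # (weight, visited_ancestors frozenset, terminal owner)

    def trace(k, weight, visited, start):
        for p in (sire[k], dam[k]):
            if p >= 0:
                trace(p, weight / 2.0, visited | {p}, start)
            else:
                paths.append((weight / 2.0, visited, k))

    n_ref = len(refped.reference_ids)
    for ind in refped.reference_ids:
        trace(ped.index_of(ind), 1.0 / n_ref, frozenset(), ped.index_of(ind))

    years = ped.df["birth_year"].to_numpy(dtype=float)
    ids = list(ped.ids)
    candidates = sorted(
        {a for _, vis, term in paths for a in vis} |
        {term for _, vis, term in paths}
    )
    selected: set[int] = set()
    p_k: dict[str, float] = {}
    remaining = list(paths)
    while remaining and candidates:
        scores = {}
        for a in candidates:
            if a in selected:
                continue
            scores[a] = sum(
                w for w, vis, term in remaining if a in vis or term == a
            )
        if not scores or max(scores.values()) <= 1e-12:
            break
        best = max(scores.values())
        tie = [a for a, s in scores.items() if s >= best - 1e-15]
        tie.sort(key=lambda a: (years[a], ids[a]))
        a = tie[0]
        selected.add(a)
        p_k[ids[a]] = scores[a]
        remaining = [
            (w, vis, term) for w, vis, term in remaining
            if a not in vis and term != a
        ]
    return pd.Series(p_k)


def enumerate_edr_genomes_exact(refped: bs.ReferencePedigree) -> float:
    """Exact founder-genome equivalents by enumerating all transmissions."""
    from itertools import product

    ped = refped.ped
    sire, dam = ped.parent_indices()
    topo = ped.topological_order()
    n = len(ped)

    meioses = [
        (k, s) for k in topo for s, p in enumerate((sire[k], dam[k])) if p >= 0
    ]
    labels = {}
    owner = {}
    for k in range(n):
        for s, p in enumerate((sire[k], dam[k])):
            if p < 0:
                lab = len(labels)
                labels[(k, s)] = lab
                owner[lab] = k
    ref_idx = [ped.index_of(i) for i in refped.reference_ids]

    surv_sum = {lab: 0.0 for lab in owner}
    n_out = 0
    for outcome in product((0, 1), repeat=len(meioses)):
        choice = dict(zip(meioses, outcome))
        alle = {}
        for k in topo:
            for s, p in enumerate((sire[k], dam[k])):
                if p < 0:
                    alle[(k, s)] = labels[(k, s)]
                else:
                    alle[(k, s)] = alle[(p, choice[(k, s)])]
        present = {alle[(k, s)] for k in ref_idx for s in (0, 1)}
        for lab in present:
            surv_sum[lab] += 1.0
        n_out += 1

    per_entity: dict[int, list[float]] = {}
    for lab, k in owner.items():
        per_entity.setdefault(k, []).append(surv_sum[lab] / n_out)
    base = bs.edr_effective(refped)
    total = 0.0
    for ind, p in base.p_i.items():
        k = ped.index_of(ind)
        r = float(np.mean(per_entity[k]))
        total += p**2 / r
    return 1.0 / total


# ---------------------------------------------------------------------------
# shared simulated bundles (session-scoped: several test files reuse them)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_config():
    return bs.SimConfig(
        n_founders=6,
        start_year=1980,
        end_year=2005,
        closure_year=1984,
        litters_per_year=6.0,
        litter_size_mean=3.0,
        sire_concentration=1.0,
        genome=[("1", 30_000_000)],
        immigrants_per_year=1,
        seed=20240915,
    )


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """One simulated breed with both panels and IBD truth."""
    ped, _ = bs.simulate_pedigree(sim_config)
    sparse, dense, truth = bs.gene_drop_genotypes(ped, sim_config)
    return {"ped": ped, "sparse": sparse, "dense": dense, "truth": truth,
            "config": sim_config}
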