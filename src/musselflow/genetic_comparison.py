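"""From connectivity to genetics: migration matrices, DOR distances, Mantel.

The decadal connectivity matrix is down-scaled to populations at the level
of settler counts (so totals are conserved), column-standardised into a
migration matrix M whose column i is the distribution of source populations
feeding receiving population i (diagonal = self-recruitment), optionally
projected over g generations as M^g, and converted into the Derived
Oceanographic Resistance (DOR): Nei's D_A distance

    D_A(i, j) = 1 - sum_k sqrt(M[k, i] * M[k, j]),

one minus the Bhattacharyya coefficient of the two source-composition
profiles, which is symmetric, zero on the diagonal and bounded in [0, 1].
The DOR is compared to an empirical pairwise F_ST matrix with a one-tailed
Mantel permutation test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity_metrics import ConnectivityMatrix


# ---------------------------------------------------------------------------
# Matrix types
# ---------------------------------------------------------------------------

@dataclass
class MigrationMatrix:
    """Column-stochastic population exchange matrix.

    values[k, i] is the fraction of settlement at population i that
    originated from population k; non-degenerate columns sum to 1, all-zero
    (degenerate) columns are flagged.
    """

    values: np.ndarray
    population_ids: list
    generations: int = 1
    degenerate: np.ndarray = field(default=None)  # bool per column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.population_ids)
        if self.values.shape != (p, p):
            raise ValueError("migration matrix must be square over populations")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        colsums = self.values.sum(axis=0)
        if self.degenerate is None:
            self.degenerate = colsums == 0
        bad = ~self.degenerate & (np.abs(colsums - 1.0) > 1e-9)
        if bad.any():
            raise ValueError("non-degenerate columns must sum to 1")


@dataclass
class DORMatrix:
    """Pairwise Derived Oceanographic Resistance distances."""

    values: np.ndarray
    population_ids: list
    generations: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("DOR must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-9):
            raise ValueError("DOR diagonal must be zero")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("DOR entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.population_ids,
                     columns=self.population_ids).to_csv(path)


@dataclass
class FstMatrix:
    """Pairwise genetic differentiation between sampled populations."""

    values: np.ndarray
    population_ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("F_ST matrix must be symmetric")
        if np.any(v < 0):
            warnings.warn("negative F_ST entries clamped to 0", stacklevel=2)
            v = np.clip(v, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @classmethod
    def from_csv(cls, path: str) -> "FstMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(), population_ids=list(df.index))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.population_ids,
                     columns=self.population_ids).to_csv(path)


def synthetic_fst_matrix(population_ids: Sequence, seed: int,
                         max_fst: float = 0.011) -> FstMatrix:
    """Synthetic stand-in for an empirical F_ST matrix (weak differentiation:
    uniform pairwise values in (0, max_fst])."""
    rng = np.random.default_rng(seed)
    p = len(population_ids)
    v = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    v[iu] = rng.uniform(0.0, max_fst, len(iu[0]))
    v = v + v.T
    return FstMatrix(values=v, population_ids=list(population_ids))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def downscale_to_populations(
    C: ConnectivityMatrix,
    site_to_population: dict,
    released_per_site: dict,
    extra_populations: Sequence = (),
) -> tuple[ConnectivityMatrix, dict]:
    """Regroup a site-level matrix to populations at settler-count level.

    Implied settler counts C[i, j] * released[i] are summed over site groups
    and re-fractionalised by group releases, so total settled counts are
    conserved (never a naive mean of fractions).  ``extra_populations``
    appends populations with no sites/releases as zero, degenerate rows and
    columns (e.g. a spat-collection beach carried as a population).
    """
    for s in C.source_ids:
        if s not in site_to_population:
            raise ValueError(f"unmapped site id {s!r}")
    pops = sorted({site_to_population[s] for s in C.source_ids})
    pops += [p for p in extra_populations if p not in pops]
    pos = {p: i for i, p in enumerate(pops)}
    rel = np.array([released_per_site[s] for s in C.source_ids], dtype=float)
    counts = C.values * rel[:, None]
    p = len(pops)
    agg = np.zeros((p, p))
    rel_pop = np.zeros(p)
    for i, src in enumerate(C.source_ids):
        pi = pos[site_to_population[src]]
        rel_pop[pi] += rel[i]
        for j, snk in enumerate(C.sink_ids):
            if snk not in site_to_population:
                raise ValueError(f"unmapped site id {snk!r}")
            agg[pi, pos[site_to_population[snk]]] += counts[i, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rel_pop[:, None] > 0, agg / rel_pop[:, None], 0.0)
    mat = ConnectivityMatrix(frac, pops, pops, kind=C.kind, years=C.years)
    return mat, {p_: rel_pop[pos[p_]] for p_ in pops}


def to_migration_matrix(P: ConnectivityMatrix | np.ndarray,
                        population_ids: Sequence | None = None) -> MigrationMatrix:
    """Column-standardise a population matrix: each column divided by its
    sum; all-zero columns stay zero and are flagged degenerate."""
    if isinstance(P, ConnectivityMatrix):
        vals = P.values
        population_ids = P.source_ids
    else:
        vals = np.asarray(P, dtype=float)
        if population_ids is None:
            population_ids = list(range(vals.shape[0]))
    if np.any(vals < 0):
        raise ValueError("population matrix must be non-negative")
    colsums = vals.sum(axis=0)
    degenerate = colsums == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(degenerate[None, :], 0.0, vals / np.where(colsums == 0, 1.0, colsums))
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} receiving population(s) with no "
                      "settlement: degenerate zero columns", stacklevel=2)
    return MigrationMatrix(m, list(population_ids), generations=1,
                           degenerate=degenerate)


def project_generations(M: MigrationMatrix, g: int) -> MigrationMatrix:
    """M^g: multi-generation exchange.  Column-stochasticity is preserved
    automatically; columns are renormalised only if numerical drift exceeds
    1e-9."""
    if g < 1:
        raise ValueError("generations must be >= 1")
    power = np.linalg.matrix_power(M.values, g)
    colsums = power.sum(axis=0)
    # settlement routed through populations whose own columns are degenerate
    # leaks mass under powers; renormalise, and re-flag columns that collapse
    degenerate = M.degenerate | (colsums <= 1e-12)
    drift = ~degenerate & (np.abs(colsums - 1.0) > 1e-9)
    if drift.any():
        power[:, drift] /= colsums[drift]
    power[:, degenerate] = 0.0
    return MigrationMatrix(power, M.population_ids, generations=g,
                           degenerate=degenerate)


def nei_da_distance(M: MigrationMatrix) -> DORMatrix:
    """Nei's D_A between the columns (source-composition profiles) of M.

    D(i, j) = 1 - sum_k sqrt(M[k, i] M[k, j]).  Degenerate columns get
    distance 1 to every other population and 0 to themselves.
    """
    cols = M.values
    bc = np.sqrt(cols).T @ np.sqrt(cols)      # Bhattacharyya coefficients
    d = 1.0 - np.clip(bc, 0.0, 1.0)
    if M.degenerate.any():
        d[M.degenerate, :] = 1.0
        d[:, M.degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DORMatrix(d, M.population_ids, generations=M.generations)


def mantel_test(A: np.ndarray, B: np.ndarray, n_perm: int = 5000,
                rng: np.random.Generator | int | None = None,
                alternative: str = "greater") -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the strict upper triangles; the p-value
    comes from ``n_perm`` simultaneous row/column permutations of B,
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for the one-tailed positive
    association default ("less"/"two-sided" available).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or B.shape != (n, n):
        raise ValueError("distance matrices must be square and equally sized")
    if n < 3:
        raise ValueError("need at least 3 items for a Mantel test")
    for name, M in (("A", A), ("B", B)):
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError(f"{name} must be symmetric")
        if np.any(np.abs(np.diag(M)) > 1e-9):
            raise ValueError(f"{name} must have a zero diagonal")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    iu = np.triu_indices(n, k=1)
    a = A[iu]

    def corr(bvec):
        return np.corrcoef(a, bvec)[0, 1]

    r_obs = corr(B[iu])
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # vectorised gather of permuted upper triangles
    bi = perms[:, iu[0]]
    bj = perms[:, iu[1]]
    bv = B[bi, bj]                                   # (n_perm, n_pairs)
    a_c = a - a.mean()
    bv_c = bv - bv.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum() * (bv_c**2).sum(axis=1))
    r_perm = (bv_c @ a_c) / np.where(denom == 0, np.inf, denom)
    if alternative == "greater":
        count = np.sum(r_perm >= r_obs - 1e-12)
    elif alternative == "less":
        count = np.sum(r_perm <= r_obs + 1e-12)
    elif alternative == "two-sided":
        count = np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    else:
        raise ValueError("alternative must be greater, less or two-sided")
    p = (1.0 + count) / (1.0 + n_perm)
    return float(r_obs), float(p)


def compare_to_genetics(
    C_decadal: ConnectivityMatrix,
    site_to_population: dict,
    released_per_site: dict,
    fst: FstMatrix,
    generations_list: Sequence[int] = (1, 10),
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Full comparison pipeline: downscale, standardise, project, DOR and
    Mantel against the F_ST matrix restricted to the shared populations."""
    pop_mat, _rel = downscale_to_populations(C_decadal, site_to_population,
                                             released_per_site)
    M1 = to_migration_matrix(pop_mat)
    shared = [p for p in fst.population_ids if p in M1.population_ids]
    if len(shared) < 3:
        raise ValueError("fewer than 3 populations shared with the F_ST matrix")
    fpos = {p: i for i, p in enumerate(fst.population_ids)}
    f_idx = [fpos[p] for p in shared]
    F = fst.values[np.ix_(f_idx, f_idx)]

    rng = np.random.default_rng(seed)
    report: dict = {"n_perm": n_perm, "seed": seed,
                    "populations": shared, "generations": {}}
    mpos = {p: i for i, p in enumerate(M1.population_ids)}
    m_idx = [mpos[p] for p in shared]
    for g in generations_list:
        Mg = project_generations(M1, g) if g > 1 else M1
        dor_full = nei_da_distance(Mg)
        D = dor_full.values[np.ix_(m_idx, m_idx)]
        dor = DORMatrix(D, shared, generations=g)
        r, p = mantel_test(D, F, n_perm=n_perm, rng=rng)
        report["generations"][g] = {"dor": dor, "mantel_r": r, "mantel_p": p}
    return report


def write_report(report: dict, path: str) -> None:
    """Serialise a compare_to_genetics report to JSON (DOR matrices inline)."""
    out = {"n_perm": report["n_perm"], "seed": report["seed"],
           "populations": [str(p) for p in report["populations"]],
           "generations": {}}
    for g, entry in report["generations"].items():
        out["generations"][str(g)] = {
            "mantel_r": entry["mantel_r"],
            "mantel_p": entry["mantel_p"],
            "dor": entry["dor"].values.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
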