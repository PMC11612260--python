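"""C-score null-model analysis under fixed-fixed sequential-swap randomization.

The C-score (Stone & Roberts) is the mean number of checkerboard units (CU)
over all unordered taxon pairs::

    CU(i, j) = (r_i - S_ij) * (r_j - S_ij)

where ``r_i`` is taxon i's occupied-site count and ``S_ij`` the number of
sites the pair shares.  High C-scores mean taxa share fewer sites than their
occupancy would allow (segregation); a C-score of zero means complete overlap.

The null distribution is generated by the sequential-swap Markov chain over
binary matrices with fixed row and column totals: random 2x2 submatrices of
the form [[1,0],[0,1]] or [[0,1],[1,0]] are flipped, which preserves both
margins.  With uniformly drawn row/column pairs this chain is symmetric and
its stationary distribution is uniform over the connected set of matrices
sharing the observed margins.

Direction convention (important): an observed C-score in the *upper* tail of
the null distribution indicates *negative* co-occurrence (segregation); the
lower tail indicates *positive* co-occurrence (aggregation).

The hot loops are numba-compiled; :func:`attempt_swap` is the plain-Python
reference implementation of the chain's single step.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .community import CommunityMatrix, StratumKey

__all__ = [
    "c_score",
    "checkerboard_units",
    "PairwiseCheckerboard",
    "attempt_swap",
    "swap_at",
    "has_swappable_submatrix",
    "null_distribution",
    "FrozenChainError",
    "ses",
    "tail_probabilities",
    "classify",
    "CScoreResult",
    "CScoreNullModel",
    "run_null_batch",
    "derive_seed",
]


class FrozenChainError(RuntimeError):
    """The swap chain cannot move: no swappable 2x2 submatrix exists."""


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _c_score_cells(cells):  # pragma: no cover - exercised via c_score
    m, n = cells.shape
    total = 0.0
    for i in range(m):
        ri = 0
        for k in range(n):
            ri += cells[i, k]
        for j in range(i + 1, m):
            rj = 0
            s = 0
            for k in range(n):
                rj += cells[j, k]
                s += cells[i, k] * cells[j, k]
            total += (ri - s) * (rj - s)
    return total / (m * (m - 1) / 2.0)


@njit(cache=True)
def _attempt_swap_inplace(cells, m, n):  # pragma: no cover
    i = np.random.randint(0, m)
    j = np.random.randint(0, m - 1)
    if j >= i:
        j += 1
    a = np.random.randint(0, n)
    b = np.random.randint(0, n - 1)
    if b >= a:
        b += 1
    ia, ib, ja, jb = cells[i, a], cells[i, b], cells[j, a], cells[j, b]
    if ia == 1 and jb == 1 and ib == 0 and ja == 0:
        cells[i, a] = 0
        cells[j, b] = 0
        cells[i, b] = 1
        cells[j, a] = 1
        return 1
    if ia == 0 and jb == 0 and ib == 1 and ja == 1:
        cells[i, a] = 1
        cells[j, b] = 1
        cells[i, b] = 0
        cells[j, a] = 0
        return 1
    return 0


@njit(cache=True)
def _has_checkerboard(cells):  # pragma: no cover
    m, n = cells.shape
    for i in range(m):
        for j in range(i + 1, m):
            i_only = False
            j_only = False
            for k in range(n):
                if cells[i, k] == 1 and cells[j, k] == 0:
                    i_only = True
                elif cells[j, k] == 1 and cells[i, k] == 0:
                    j_only = True
                if i_only and j_only:
                    break
            if i_only and j_only:
                return True
    return False


@njit(cache=True)
def _run_chain(cells, n_samples, burn_in, thin, seed):  # pragma: no cover
    """Burn in by successful-swap count, then record one C-score every
    ``thin`` attempted swaps.  Mutates ``cells``; returns sampled C-scores
    and the total attempted-swap / successful-swap counts."""
    np.random.seed(seed)
    m, n = cells.shape
    sims = np.empty(n_samples)
    attempts = 0
    successes = 0
    while successes < burn_in:
        successes += _attempt_swap_inplace(cells, m, n)
        attempts += 1
    for s in range(n_samples):
        for _ in range(thin):
            successes += _attempt_swap_inplace(cells, m, n)
            attempts += 1
        sims[s] = _c_score_cells(cells)
    return sims, attempts, successes


@njit(cache=True)
def _randomize_cells(cells, n_attempts, seed):  # pragma: no cover
    """Advance the chain by a fixed number of *attempted* swaps.

    Counting attempts (not successes) keeps the stopping rule independent of
    the state's neighbor count, so the mixed state is a draw from the
    chain's uniform stationary distribution; stopping after a fixed number
    of successful swaps instead would over-sample states with few swappable
    submatrices."""
    np.random.seed(seed)
    m, n = cells.shape
    for _ in range(n_attempts):
        _attempt_swap_inplace(cells, m, n)


# --------------------------------------------------------------------------
# observed-matrix statistics
# --------------------------------------------------------------------------

def _as_cells(matrix: CommunityMatrix | np.ndarray) -> np.ndarray:
    cells = matrix.cells if isinstance(matrix, CommunityMatrix) else np.asarray(matrix)
    return np.ascontiguousarray(cells, dtype=np.int8)


def c_score(matrix: CommunityMatrix | np.ndarray) -> float:
    """Mean checkerboard units over all unordered taxon pairs."""
    cells = _as_cells(matrix)
    if cells.shape[0] < 2:
        raise ValueError("C-score requires at least 2 taxa")
    return float(_c_score_cells(cells))


@dataclass
class PairwiseCheckerboard:
    """Per-pair checkerboard units and per-taxon aggregates.

    ``pairs`` is indexed by (taxon_i, taxon_j) with columns
    [cu, shared, r_i, r_j]; ``per_taxon`` is indexed by taxon with columns
    [cu_sum, cu_mean] over that taxon's M-1 pairs.
    """

    pairs: pd.DataFrame
    per_taxon: pd.DataFrame

    @property
    def c_score(self) -> float:
        return float(self.pairs["cu"].mean())


def checkerboard_units(matrix: CommunityMatrix | np.ndarray) -> PairwiseCheckerboard:
    """Per-pair CU table and per-taxon CU sums/means.

    The mean of the pair table equals :func:`c_score`; a taxon's CU sum is
    the diagnostic the mechanism step uses to spot "driver" taxa.
    """
    cells = _as_cells(matrix).astype(np.int64)
    m = cells.shape[0]
    if m < 2:
        raise ValueError("checkerboard_units requires at least 2 taxa")
    taxa = (
        matrix.taxa
        if isinstance(matrix, CommunityMatrix)
        else [f"t{i}" for i in range(m)]
    )
    r = cells.sum(axis=1)
    shared = cells @ cells.T
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu, ju = np.triu_indices(m, k=1)
    pairs = pd.DataFrame(
        {
            "cu": cu[iu, ju].astype(float),
            "shared": shared[iu, ju],
            "r_i": r[iu],
            "r_j": r[ju],
        },
        index=pd.MultiIndex.from_arrays(
            [np.asarray(taxa)[iu], np.asarray(taxa)[ju]],
            names=["taxon_i", "taxon_j"],
        ),
    )
    np.fill_diagonal(cu, 0)
    sums = cu.sum(axis=1).astype(float)
    per_taxon = pd.DataFrame(
        {"cu_sum": sums, "cu_mean": sums / (m - 1)}, index=pd.Index(taxa, name="taxon")
    )
    return PairwiseCheckerboard(pairs=pairs, per_taxon=per_taxon)


# --------------------------------------------------------------------------
# sequential swap
# --------------------------------------------------------------------------

def swap_at(cells: np.ndarray, i: int, j: int, a: int, b: int) -> bool:
    """Flip the 2x2 submatrix at rows (i, j) x columns (a, b) if it is a
    checkerboard; returns whether a swap happened.  In place."""
    sub = cells[np.ix_([i, j], [a, b])]
    if (sub == [[1, 0], [0, 1]]).all() or (sub == [[0, 1], [1, 0]]).all():
        cells[np.ix_([i, j], [a, b])] = 1 - sub
        return True
    return False


def attempt_swap(cells: np.ndarray, rng: np.random.Generator) -> bool:
    """One sequential-swap step: draw two distinct rows and two distinct
    columns uniformly and flip the submatrix if it is a checkerboard.

    Mutates ``cells``; row and column totals are always preserved.
    Reference implementation of the compiled chain step.
    """
    m, n = cells.shape
    if m < 2 or n < 2:
        return False
    i, j = rng.choice(m, size=2, replace=False)
    a, b = rng.choice(n, size=2, replace=False)
    return swap_at(cells, int(i), int(j), int(a), int(b))


def has_swappable_submatrix(matrix: CommunityMatrix | np.ndarray) -> bool:
    """Whether any 2x2 checkerboard submatrix exists (chain can move)."""
    cells = _as_cells(matrix)
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        return False
    return bool(_has_checkerboard(cells))


def default_burn_in(matrix: CommunityMatrix | np.ndarray) -> int:
    """10 x (rows x columns) successful swaps, at least 1000."""
    cells = _as_cells(matrix)
    return max(1000, 10 * cells.shape[0] * cells.shape[1])


def default_thin(matrix: CommunityMatrix | np.ndarray) -> int:
    """rows x columns attempted swaps between retained samples."""
    cells = _as_cells(matrix)
    return cells.shape[0] * cells.shape[1]


def null_distribution(
    matrix: CommunityMatrix | np.ndarray,
    n_iter: int = 5000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n_iter`` C-scores from the fixed-fixed swap chain.

    The chain starts at the observed matrix, burns in for ``burn_in``
    *successful* swaps, then records one C-score every ``thin`` *attempted*
    swaps.  Raises :class:`FrozenChainError` if no swappable submatrix
    exists anywhere (the result is then unusable, not p = 1).
    """
    cells = _as_cells(matrix).copy()
    if cells.shape[0] < 2:
        raise ValueError("null_distribution requires at least 2 taxa")
    if not _has_checkerboard(cells):
        raise FrozenChainError(
            "no swappable 2x2 submatrix: chain frozen, matrix unusable"
        )
    if burn_in is None:
        burn_in = default_burn_in(cells)
    if thin is None:
        thin = default_thin(cells)
    sims, _, _ = _run_chain(cells, int(n_iter), int(burn_in), int(thin), int(seed))
    return sims


# --------------------------------------------------------------------------
# effect size, tails, classification
# --------------------------------------------------------------------------

def ses(observed_c: float, sims: Sequence[float]) -> float:
    """Standardized effect size: (observed - mean(null)) / sd(null).

    Sample standard deviation (ddof=1).  Returns NaN when the null
    distribution has zero variance (SES undefined).
    """
    sims = np.asarray(sims, dtype=float)
    if sims.size == 0:
        raise ValueError("ses requires a non-empty null sample")
    sd = sims.std(ddof=1) if sims.size > 1 else 0.0
    if sd == 0:
        return float("nan")
    return float((observed_c - sims.mean()) / sd)


def tail_probabilities(
    observed_c: float, sims: Sequence[float], plus_one: bool = False
) -> tuple[float, float]:
    """(p_le, p_ge): fraction of null C-scores <=, >= the observed value.

    Ties count in both tails, so p_le + p_ge >= 1.  With ``plus_one`` the
    conservative (count+1)/(n+1) convention is used instead of count/n.
    """
    sims = np.asarray(sims, dtype=float)
    if sims.size == 0:
        raise ValueError("tail_probabilities requires a non-empty null sample")
    n = sims.size
    le = int((sims <= observed_c).sum())
    ge = int((sims >= observed_c).sum())
    if plus_one:
        return (le + 1) / (n + 1), (ge + 1) / (n + 1)
    return le / n, ge / n


def classify(p_le: float, p_ge: float, alpha: float = 0.05) -> str:
    """Two-tailed classification of co-occurrence structure.

    ``negative`` (segregated) when the observed C-score sits in the upper
    alpha/2 tail of the null, ``positive`` (aggregated) in the lower tail,
    ``random`` otherwise.  If both tails qualify (pathological ties) the
    matrix is reported random.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    neg = p_ge <= alpha / 2
    pos = p_le <= alpha / 2
    if neg and pos:
        return "random"
    if neg:
        return "negative"
    if pos:
        return "positive"
    return "random"


@dataclass
class CScoreResult:
    """Null-model test result for one community matrix."""

    observed_c: float
    sim_mean: float
    sim_sd: float
    ses: float
    p_le: float
    p_ge: float
    n_iterations: int
    burn_in: int
    thin: int
    seed: int
    classification: str
    key: StratumKey | None = None
    n_taxa: int | None = None
    n_sites: int | None = None
    sims: np.ndarray | None = field(default=None, repr=False)

    @property
    def ses_defined(self) -> bool:
        return np.isfinite(self.ses)

    @property
    def usable(self) -> bool:
        return self.classification != "unusable"

    def reclassify(self, alpha: float) -> str:
        if not self.usable:
            return "unusable"
        return classify(self.p_le, self.p_ge, alpha)

    def summary(self) -> str:
        lines = ["C-score null-model analysis (fixed-fixed sequential swap)"]
        if self.key is not None:
            lines.append(f"  matrix          {self.key}")
        if self.n_taxa is not None:
            lines.append(f"  size            {self.n_taxa} taxa x {self.n_sites} sites")
        lines += [
            f"  observed C      {self.observed_c:.4f}",
            f"  null mean (sd)  {self.sim_mean:.4f} ({self.sim_sd:.4f})",
            f"  SES             {self.ses:.4f}",
            f"  p (obs <= exp)  {self.p_le:.4f}",
            f"  p (obs >= exp)  {self.p_ge:.4f}",
            f"  iterations      {self.n_iterations} "
            f"(burn-in {self.burn_in}, thin {self.thin}, seed {self.seed})",
            f"  classification  {self.classification}",
        ]
        return "\n".join(lines)


class CScoreNullModel:
    """Null-model test of co-occurrence structure for one community matrix.

    Parameters
    ----------
    matrix
        Cleaned community matrix (or bare 0/1 ndarray).
    n_iterations
        Number of null C-scores to sample (study default 5000).
    burn_in, thin
        Chain schedule; defaults are 10*(m*n) successful swaps (min 1000)
        and m*n attempted swaps between samples.

    ``fit(seed)`` runs the chain and returns a :class:`CScoreResult`.
    """

    def __init__(
        self,
        matrix: CommunityMatrix | np.ndarray,
        n_iterations: int = 5000,
        burn_in: int | None = None,
        thin: int | None = None,
    ):
        self.matrix = matrix
        self.cells = _as_cells(matrix)
        if self.cells.shape[0] < 2:
            raise ValueError("need at least 2 taxa")
        self.n_iterations = int(n_iterations)
        self.burn_in = int(burn_in) if burn_in is not None else default_burn_in(self.cells)
        self.thin = int(thin) if thin is not None else default_thin(self.cells)

    def fit(
        self, seed: int = 0, alpha: float = 0.05, keep_sims: bool = False
    ) -> CScoreResult:
        key = self.matrix.key if isinstance(self.matrix, CommunityMatrix) else None
        obs = c_score(self.cells)
        common = dict(
            observed_c=obs,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=int(seed),
            key=key,
            n_taxa=self.cells.shape[0],
            n_sites=self.cells.shape[1],
        )
        try:
            sims = null_distribution(
                self.cells, self.n_iterations, self.burn_in, self.thin, seed
            )
        except FrozenChainError:
            return CScoreResult(
                sim_mean=float("nan"),
                sim_sd=float("nan"),
                ses=float("nan"),
                p_le=float("nan"),
                p_ge=float("nan"),
                classification="unusable",
                **common,
            )
        p_le, p_ge = tail_probabilities(obs, sims)
        return CScoreResult(
            sim_mean=float(sims.mean()),
            sim_sd=float(sims.std(ddof=1)),
            ses=ses(obs, sims),
            p_le=p_le,
            p_ge=p_ge,
            classification=classify(p_le, p_ge, alpha),
            sims=sims if keep_sims else None,
            **common,
        )


# --------------------------------------------------------------------------
# batch driver
# --------------------------------------------------------------------------

def derive_seed(master_seed: int, key: StratumKey | str) -> int:
    """Deterministic per-matrix seed from a master seed and stratum key.

    Stable across runs and platforms; adding strata never perturbs the
    seeds of existing ones.
    """
    digest = hashlib.blake2b(
        f"{master_seed}|{key}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def run_null_batch(
    matrices: Sequence[CommunityMatrix],
    n_iterations: int = 5000,
    alpha: float = 0.05,
    master_seed: int = 0,
    burn_in: int | None = None,
    thin: int | None = None,
) -> pd.DataFrame:
    """Run the null model over many matrices; one result row per matrix.

    Columns mirror the per-stratum reporting layout: stratum fields, matrix
    size, observed C-score, tail probabilities, SES, classification, and the
    per-matrix seed derived from the master seed.
    """
    rows = []
    for m in matrices:
        seed = derive_seed(master_seed, m.key)
        res = CScoreNullModel(
            m, n_iterations=n_iterations, burn_in=burn_in, thin=thin
        ).fit(seed=seed, alpha=alpha)
        rows.append(
            {
                "year": m.key.year,
                "ecoregion": m.key.ecoregion,
                "vegetation": m.key.vegetation,
                "unit_type": m.key.unit_type,
                "unit": m.key.unit_label,
                "n_taxa": m.n_taxa,
                "n_sites": m.n_sites,
                "c_score": res.observed_c,
                "sim_mean": res.sim_mean,
                "sim_sd": res.sim_sd,
                "ses": res.ses,
                "p_le": res.p_le,
                "p_ge": res.p_ge,
                "classification": res.classification,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
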