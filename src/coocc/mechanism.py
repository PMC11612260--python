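"""Mechanism inference for non-randomly structured community matrices.

A significant C-score says a matrix is structured, not why.  This module
implements the decision framework that isolates candidate mechanisms:

* negative (segregated) matrices: first compare pollution-tolerance scores
  of the taxa driving the checkerboard signal; if tolerances are similar,
  test whether the sites occupied by the driver taxa differ environmentally
  (PCA to three components, then one-way PERMANOVA on the presence
  grouping).  Only when tolerances are similar *and* habitats homogeneous is
  competitive exclusion left as the parsimonious explanation.
* positive (aggregated) matrices: shared habitat affinity is tested first,
  then shared tolerance; biological homogenization remains by elimination.

Missing inputs propagate as ``unknown`` calls and an ``indeterminate``
verdict rather than a guess.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .community import CommunityMatrix, StratumKey
from .nullmodel import PairwiseCheckerboard, checkerboard_units

logger = logging.getLogger("coocc")

#: Environmental variable vocabulary (superset; availability is data-driven).
ENV_VARIABLES = (
    "dissolved_oxygen",
    "temperature",
    "ph",
    "specific_conductance",
    "total_alkalinity",
    "turbidity",
    "soluble_reactive_phosphorus",
    "ammonia_ammonium",
    "chlorophyll_a",
    "total_phosphorus",
    "total_nitrogen",
    "nitrate_nitrite",
    "sumrank",
    "fetch",
)

TOLERANCE_CALLS = ("similar", "differential", "unknown")
HABITAT_CALLS = ("homogeneous", "different", "unknown")
VERDICTS = (
    "competitive_exclusion",
    "differential_tolerance",
    "differential_habitat",
    "shared_habitat",
    "shared_tolerance",
    "biological_homogenization",
    "neutral",
    "indeterminate",
)


# --------------------------------------------------------------------------
# driver taxa
# --------------------------------------------------------------------------

@dataclass
class DriverTaxa:
    """Taxa carrying a disproportionate share of checkerboard units."""

    taxa: list[str]
    z_scores: pd.Series
    below_threshold: bool = False  # fallback single-max contributor used

    def __iter__(self):
        return iter(self.taxa)

    def __len__(self):
        return len(self.taxa)


def flag_driver_taxa(
    cb: PairwiseCheckerboard, z_threshold: float = 2.0
) -> DriverTaxa:
    """Identify taxa with considerably more checkerboard units than the rest.

    A taxon is a driver when the z-score of its per-taxon CU sum (sample sd
    over the matrix's taxa) exceeds ``z_threshold``.  If CU sums carry no
    variation (all equal, e.g. full overlap), no driver exists.  If there is
    variation but no taxon crosses the threshold, the single largest
    contributor is returned flagged ``below_threshold``.
    """
    sums = cb.per_taxon["cu_sum"]
    sd = sums.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return DriverTaxa(taxa=[], z_scores=sums * 0.0)
    z = (sums - sums.mean()) / sd
    flagged = list(z.index[z > z_threshold])
    if flagged:
        return DriverTaxa(taxa=flagged, z_scores=z)
    top = str(sums.idxmax())
    logger.info(
        "flag_driver_taxa: no taxon above z=%.1f; falling back to max "
        "contributor %s (z=%.2f)", z_threshold, top, z[top],
    )
    return DriverTaxa(taxa=[top], z_scores=z, below_threshold=True)


def partner_taxa(cb: PairwiseCheckerboard, driver: str) -> list[str]:
    """Taxa forming at least one checkerboard unit with ``driver``."""
    pairs = cb.pairs.reset_index()
    mask = (pairs["taxon_i"] == driver) | (pairs["taxon_j"] == driver)
    sub = pairs[mask & (pairs["cu"] > 0)]
    partners = set(sub["taxon_i"]) | set(sub["taxon_j"])
    partners.discard(driver)
    return sorted(partners)


# --------------------------------------------------------------------------
# pollution tolerance
# --------------------------------------------------------------------------

@dataclass
class ToleranceCall:
    call: str  # similar | differential | unknown
    gaps: pd.DataFrame  # columns: driver, partner, gap (NaN when unscored)


def tolerance_separation(
    driver_taxa: list[str],
    partners: list[str],
    tolerances: pd.Series | dict,
    gap_threshold: float = 3.0,
) -> ToleranceCall:
    """Compare Hilsenhoff tolerance scores of drivers vs their partners.

    ``differential`` when the absolute tolerance gap is at least
    ``gap_threshold`` (on the 0-10 scale) for the majority of scored
    driver-partner pairs; ``similar`` otherwise; ``unknown`` when more than
    half the involved taxa lack scores.  Raw gaps are always returned so the
    rule can be overridden by inspection.
    """
    tol = pd.Series(tolerances, dtype=float)
    involved = sorted(set(driver_taxa) | set(partners))
    if not involved or not driver_taxa or not partners:
        return ToleranceCall("unknown", pd.DataFrame(columns=["driver", "partner", "gap"]))
    scored = [t for t in involved if t in tol.index and np.isfinite(tol.get(t, np.nan))]
    rows = []
    for d in driver_taxa:
        for p in partners:
            if p == d:
                continue
            gap = np.nan
            if d in scored and p in scored:
                gap = abs(float(tol[d]) - float(tol[p]))
            rows.append({"driver": d, "partner": p, "gap": gap})
    gaps = pd.DataFrame(rows)
    if len(scored) <= len(involved) / 2:
        return ToleranceCall("unknown", gaps)
    valid = gaps["gap"].dropna()
    if valid.empty:
        return ToleranceCall("unknown", gaps)
    call = "differential" if (valid >= gap_threshold).mean() > 0.5 else "similar"
    return ToleranceCall(call, gaps)


# --------------------------------------------------------------------------
# environmental PCA
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Standardized PCA of site environmental data (prcomp semantics)."""

    loadings: pd.DataFrame  # variables x components
    sdev: np.ndarray
    proportion_variance: np.ndarray
    scores: pd.DataFrame  # sites x components
    dropped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Environmental PCA (standardized variables)"]
        for k in range(len(self.sdev)):
            lines.append(
                f"  PC{k + 1}: sd={self.sdev[k]:.4f} "
                f"prop.var={self.proportion_variance[k]:.4f}"
            )
        if self.dropped:
            lines.append("  dropped (constant/missing): " + ", ".join(self.dropped))
        return "\n".join(lines)


def pca_environment(env: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Reduce site environmental data to principal components.

    ``env`` is sites x variables.  Variables with any missing value are
    dropped (complete-case by variable), as are constant variables (warned).
    Columns are standardized to zero mean and unit variance (sd with n-1);
    the decomposition is then of the correlation structure.  Sign
    convention: the largest-magnitude loading in each component is positive.
    """
    env = env.astype(float)
    dropped = [c for c in env.columns if env[c].isna().any()]
    if dropped:
        logger.info("pca_environment: dropping incomplete variables: %s", dropped)
    work = env.drop(columns=dropped)
    constant = [c for c in work.columns if work[c].std(ddof=1) == 0 or len(work) < 2]
    if constant:
        logger.warning("pca_environment: dropping constant variables: %s", constant)
        work = work.drop(columns=constant)
        dropped += constant
    n_sites, n_vars = work.shape
    if n_sites < 3:
        raise ValueError("pca_environment requires at least 3 sites")
    if n_vars < 2:
        raise ValueError("fewer than 2 usable environmental variables")

    x = (work - work.mean()) / work.std(ddof=1)
    u, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
    sdev = s / math.sqrt(n_sites - 1)
    rank = int((sdev > 1e-10).sum())
    k = min(n_components, rank)
    if k < n_components:
        logger.warning(
            "pca_environment: only %d non-degenerate components (requested %d)",
            k, n_components,
        )
    loadings = vt[:k].T  # variables x k
    # fix signs so each component's largest-magnitude loading is positive
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
    scores = x.to_numpy() @ loadings
    total_var = float(n_vars)  # standardized variables each contribute 1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=work.columns, columns=comp_names),
        sdev=sdev[:k],
        proportion_variance=sdev[:k] ** 2 / total_var,
        scores=pd.DataFrame(scores, index=work.index, columns=comp_names),
        dropped=dropped,
    )


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """One-way PERMANOVA (Euclidean) on site ordination scores."""

    pseudo_f: float
    p: float
    n_permutations: int
    group_sizes: list[int]
    seed: int
    method: str = "permutation"  # or "exact"
    indeterminate: bool = False  # all points identical
    infinite_f: bool = False  # SS_within = 0 with SS_between > 0

    def summary(self) -> str:
        f = "inf" if self.infinite_f else f"{self.pseudo_f:.4f}"
        return (
            "PERMANOVA (Euclidean, one-way)\n"
            f"  groups         {self.group_sizes}\n"
            f"  pseudo-F       {f}\n"
            f"  p              {self.p:.4f} ({self.method}, "
            f"{self.n_permutations} permutations)"
        )


def _pseudo_f_stats(x: np.ndarray, membership: np.ndarray, sizes: np.ndarray):
    """Vectorized pseudo-F for many binary 2+-group labelings.

    ``membership`` is (n_labelings, n_points, g) one-hot; returns F array.
    """
    n, _ = x.shape
    g = sizes.size
    grand = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    # group sums per labeling: (L, g, k)
    sums = np.einsum("lng,nk->lgk", membership, x)
    means = sums / sizes[None, :, None]
    ss_between = (sizes[None, :, None] * (means - grand[None, None, :]) ** 2).sum(
        axis=(1, 2)
    )
    ss_within = ss_total - ss_between
    df_b = g - 1
    df_w = n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_within


def permanova(
    scores: pd.DataFrame | np.ndarray,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA with Euclidean distance on ordination scores.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(N-g)); the permutation p is
    (#{F_perm >= F_obs} + 1)/(n_permutations + 1) over uniformly random
    relabelings preserving group sizes.  For two groups, when the number of
    distinct relabelings C(N, n1) is within ``n_permutations`` the full
    enumeration is used instead (``method='exact'``; p = count/total with no
    +1 correction, the observed labeling being among those enumerated).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(grouping)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("grouping length must match number of sites")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = uniq.size
    sizes = np.bincount(codes)
    if g < 2 or (sizes == 0).any():
        raise ValueError("permanova requires at least two non-empty groups")
    n = x.shape[0]
    if n < 3:
        raise ValueError("permanova requires at least 3 sites")

    if np.allclose(x, x[0]):
        return PermanovaResult(
            pseudo_f=float("nan"), p=1.0, n_permutations=0,
            group_sizes=sizes.tolist(), seed=seed, indeterminate=True,
        )

    def one_hot(code_rows: np.ndarray) -> np.ndarray:
        return np.eye(g)[code_rows]  # (L, n, g)

    f_obs, _, ss_w = _pseudo_f_stats(x, one_hot(codes[None, :]), sizes)
    infinite = bool(ss_w[0] <= 1e-12)
    f_obs_val = float("inf") if infinite else float(f_obs[0])

    n_exhaustive = math.comb(n, int(sizes[0])) if g == 2 else None
    use_exact = (
        g == 2
        and n_exhaustive is not None
        and (method == "exact" or (method == "auto" and n_exhaustive <= n_permutations))
    )
    if method not in ("auto", "exact", "permutation"):
        raise ValueError("method must be auto, exact, or permutation")

    if use_exact:
        perms = np.ones((n_exhaustive, n), dtype=int)
        for row, idx in enumerate(combinations(range(n), int(sizes[0]))):
            perms[row, list(idx)] = 0
        f_perm, _, _ = _pseudo_f_stats(x, one_hot(perms), sizes)
        f_cmp = np.where(np.isfinite(f_perm), f_perm, np.inf)
        count = int((f_cmp >= (f_obs_val - 1e-12)).sum()) if not infinite else int(
            np.isinf(f_cmp).sum()
        )
        return PermanovaResult(
            pseudo_f=f_obs_val,
            p=count / n_exhaustive,
            n_permutations=n_exhaustive,
            group_sizes=sizes.tolist(),
            seed=seed,
            method="exact",
            infinite_f=infinite,
        )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    f_perm, _, _ = _pseudo_f_stats(x, one_hot(perms), sizes)
    f_cmp = np.where(np.isfinite(f_perm), f_perm, np.inf)
    if infinite:
        count = int(np.isinf(f_cmp).sum())
    else:
        count = int((f_cmp >= (f_obs_val - 1e-12)).sum())
    return PermanovaResult(
        pseudo_f=f_obs_val,
        p=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        group_sizes=sizes.tolist(),
        seed=seed,
        method="permutation",
        infinite_f=infinite,
    )


# --------------------------------------------------------------------------
# decision framework
# --------------------------------------------------------------------------

@dataclass
class MechanismVerdict:
    """Decision-framework label for one analyzed matrix."""

    key: StratumKey | None
    classification: str
    driver_taxa: list[str]
    tolerance_call: str
    habitat_call: str
    verdict: str
    details: dict = field(default_factory=dict)


def decide_mechanism(
    classification: str,
    tolerance_call: str = "unknown",
    habitat_call: str = "unknown",
    key: StratumKey | None = None,
    driver_taxa: list[str] | None = None,
    details: dict | None = None,
) -> MechanismVerdict:
    """Pure decision function mapping the three calls to a verdict.

    negative branch (tolerance first, then habitat):
        differential tolerance -> differential_tolerance;
        similar tolerance + different habitat -> differential_habitat;
        similar tolerance + homogeneous habitat -> competitive_exclusion;
        unknown tolerance, or similar tolerance with unknown habitat
        -> indeterminate.
    positive branch (habitat first):
        homogeneous (shared) habitat -> shared_habitat;
        different habitat + similar tolerance -> shared_tolerance;
        different habitat otherwise -> biological_homogenization (by
        elimination: aggregation without shared habitat affinity);
        unknown habitat -> indeterminate.
    random -> neutral; unusable -> indeterminate.
    """
    if tolerance_call not in TOLERANCE_CALLS:
        raise ValueError(f"tolerance_call must be one of {TOLERANCE_CALLS}")
    if habitat_call not in HABITAT_CALLS:
        raise ValueError(f"habitat_call must be one of {HABITAT_CALLS}")

    if classification == "random":
        verdict = "neutral"
    elif classification == "negative":
        if tolerance_call == "differential":
            verdict = "differential_tolerance"
        elif tolerance_call == "unknown":
            verdict = "indeterminate"
        elif habitat_call == "different":
            verdict = "differential_habitat"
        elif habitat_call == "homogeneous":
            verdict = "competitive_exclusion"
        else:
            verdict = "indeterminate"
    elif classification == "positive":
        if habitat_call == "homogeneous":
            verdict = "shared_habitat"
        elif habitat_call == "unknown":
            verdict = "indeterminate"
        elif tolerance_call == "similar":
            verdict = "shared_tolerance"
        else:
            verdict = "biological_homogenization"
    else:  # unusable or unknown classification
        verdict = "indeterminate"

    return MechanismVerdict(
        key=key,
        classification=classification,
        driver_taxa=list(driver_taxa or []),
        tolerance_call=tolerance_call,
        habitat_call=habitat_call,
        verdict=verdict,
        details=details or {},
    )


def analyze_matrix(
    matrix: CommunityMatrix,
    classification: str,
    env: pd.DataFrame | None = None,
    tolerances: pd.Series | dict | None = None,
    z_threshold: float = 2.0,
    gap_threshold: float = 3.0,
    n_permutations: int = 999,
    habitat_alpha: float = 0.05,
    seed: int = 0,
) -> MechanismVerdict:
    """Full mechanism work-up for one classified matrix.

    ``env`` is a sites x variables table restricted to the matrix's sites
    (missing table -> habitat call unknown); ``tolerances`` maps taxon ->
    Hilsenhoff score.  One PERMANOVA is run per driver taxon's presence
    grouping; the habitat call is ``different`` when any of them is
    significant at ``habitat_alpha``.
    """
    details: dict = {}
    if classification in ("random", "unusable"):
        return decide_mechanism(classification, key=matrix.key, details=details)

    cb = checkerboard_units(matrix)
    drivers = flag_driver_taxa(cb, z_threshold=z_threshold)
    details["driver_z_scores"] = drivers.z_scores.to_dict()
    details["driver_below_threshold"] = drivers.below_threshold

    partners: list[str] = sorted(
        {p for d in drivers for p in partner_taxa(cb, d)} - set(drivers.taxa)
    )
    details["partner_taxa"] = partners

    if tolerances is None:
        tol_call = ToleranceCall(
            "unknown", pd.DataFrame(columns=["driver", "partner", "gap"])
        )
    else:
        tol_call = tolerance_separation(
            drivers.taxa, partners, tolerances, gap_threshold=gap_threshold
        )
    details["tolerance_gaps"] = tol_call.gaps.to_dict("records")

    habitat_call = "unknown"
    if env is not None and drivers.taxa:
        try:
            pca = pca_environment(env.loc[matrix.sites])
        except (ValueError, KeyError) as exc:
            logger.warning("analyze_matrix(%s): PCA failed: %s", matrix.key, exc)
            pca = None
        if pca is not None:
            details["pca_proportion_variance"] = pca.proportion_variance.tolist()
            tests = {}
            for d in drivers.taxa:
                present = np.asarray(
                    matrix.cells[matrix.taxa.index(d)], dtype=bool
                )
                if present.all() or not present.any():
                    continue
                res = permanova(
                    pca.scores.to_numpy(),
                    present.astype(int),
                    n_permutations=n_permutations,
                    seed=seed,
                )
                if min(res.group_sizes) == 1:
                    logger.info(
                        "analyze_matrix(%s): singleton presence group for %s "
                        "(low power)", matrix.key, d,
                    )
                tests[d] = {
                    "pseudo_f": res.pseudo_f,
                    "p": res.p,
                    "group_sizes": res.group_sizes,
                    "method": res.method,
                }
            details["permanova"] = tests
            if tests:
                min_p = min(t["p"] for t in tests.values())
                habitat_call = "different" if min_p <= habitat_alpha else "homogeneous"

    return decide_mechanism(
        classification,
        tolerance_call=tol_call.call,
        habitat_call=habitat_call,
        key=matrix.key,
        driver_taxa=drivers.taxa,
        details=details,
    )
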