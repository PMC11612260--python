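"""Synthetic occurrence, environment, and tolerance data with known structure.

Every generator emulates a feature of the wetland study design: binary
matrices with heterogeneous margins inside the observed size envelope
(5-66 taxa x 4-24 sites), optional planted segregation (mutually exclusive
taxon pairs, Diamond-style checkerboards) or aggregation, environmental
tables with optional mean shifts at focal sites, and tolerance tables with
similar or separated Hilsenhoff scores.  Ground truth is recorded alongside
each dataset so the full pipeline can be validated end to end without any
field data.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityMatrix, StratumKey
from .mechanism import ENV_VARIABLES
from .nullmodel import _randomize_cells, derive_seed

__all__ = [
    "gale_ryser_feasible",
    "canonical_matrix",
    "random_fixed_marginal_matrix",
    "plant_segregation",
    "generate_env",
    "StratumSpec",
    "default_plan",
    "generate_study",
    "write_study",
]


def gale_ryser_feasible(row_totals, col_totals) -> bool:
    """Gale-Ryser test: does a binary matrix with these margins exist?"""
    r = np.sort(np.asarray(row_totals, dtype=int))[::-1]
    c = np.asarray(col_totals, dtype=int)
    if r.sum() != c.sum():
        return False
    if (r < 0).any() or (c < 0).any():
        return False
    if len(c) and r.max(initial=0) > len(c):
        return False
    if len(r) and c.max(initial=0) > len(r):
        return False
    for k in range(1, len(r) + 1):
        if r[:k].sum() > np.minimum(c, k).sum():
            return False
    return True


def canonical_matrix(row_totals, col_totals) -> np.ndarray:
    """Deterministic feasible matrix with the requested margins (Ryser fill).

    Rows are filled greedily into the columns with the largest remaining
    capacity.  Raises if the margins violate the Gale-Ryser condition.
    """
    r = np.asarray(row_totals, dtype=int)
    c = np.asarray(col_totals, dtype=int)
    if not gale_ryser_feasible(r, c):
        raise ValueError(
            "infeasible margins: row/column totals violate the Gale-Ryser "
            f"condition (row sum {r.sum()}, column sum {c.sum()})"
        )
    m, n = len(r), len(c)
    cells = np.zeros((m, n), dtype=np.int8)
    remaining = c.astype(int).copy()
    for i in np.argsort(-r, kind="stable"):
        cols = np.argsort(-remaining, kind="stable")[: r[i]]
        cells[i, cols] = 1
        remaining[cols] -= 1
    assert (cells.sum(axis=1) == r).all() and (cells.sum(axis=0) == c).all()
    return cells


def random_fixed_marginal_matrix(
    row_totals,
    col_totals,
    rng: np.random.Generator,
    key: StratumKey | None = None,
    mixing_attempts: int | None = None,
) -> CommunityMatrix:
    """Sample a binary matrix with exactly the requested margins.

    Built from the canonical Ryser fill and mixed by a long sequential-swap
    run (default 50 x m x n attempted swaps, at least 10,000).  With uniform
    2x2 proposals the chain is symmetric, so its stationary distribution is
    uniform over the margin class; mixing is measured in attempted swaps
    because a successful-swap stopping rule would bias the draw toward
    states with few swappable submatrices.
    """
    cells = canonical_matrix(row_totals, col_totals)
    m, n = cells.shape
    if mixing_attempts is None:
        mixing_attempts = max(10_000, 50 * m * n)
    from .nullmodel import has_swappable_submatrix

    if has_swappable_submatrix(cells):
        seed = int(rng.integers(0, 2**31))
        _randomize_cells(cells, int(mixing_attempts), seed)
    if key is None:
        key = StratumKey(0, "LS", "bulrush", "trophic", "simulated")
    return CommunityMatrix(
        key=key,
        taxa=[f"taxon_{i:02d}" for i in range(m)],
        sites=[f"site_{j:02d}" for j in range(n)],
        cells=cells,
    )


def plant_segregation(
    n_taxa: int,
    n_sites: int,
    n_pairs: int,
    fill: float = 0.5,
    rng: np.random.Generator | None = None,
    leakage: float = 0.0,
    key: StratumKey | None = None,
) -> CommunityMatrix:
    """Binary matrix with ``n_pairs`` mutually exclusive taxon pairs planted.

    The sites are split once into two disjoint random halves shared by all
    planted pairs (the canonical two-guild checkerboard, the strongest form
    of the pattern): pair member A occupies one half, member B the other, so
    each pair's shared-site count is 0 and it contributes
    floor(n/2)*ceil(n/2) checkerboard units.  ``leakage`` softens the
    pattern by moving each planted presence into the opposite half with that
    probability.  Remaining taxa are Bernoulli(``fill``) noise (re-drawn if
    a row comes up empty).  Planted pairs are recorded in the cleanup-log
    metadata for truth tracking.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_pairs > n_taxa // 2:
        raise ValueError("n_pairs must be <= n_taxa / 2")
    if n_pairs > 0 and n_sites < 2:
        raise ValueError("need at least 2 sites to plant a pair")
    cells = np.zeros((n_taxa, n_sites), dtype=np.int8)
    planted: list[tuple[int, int]] = []
    order = rng.permutation(n_sites)
    half = n_sites // 2
    set_a, set_b = order[:half], order[half:]
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1
        cells[a, set_a] = 1
        cells[b, set_b] = 1
        if leakage > 0:
            for row, own, other in ((a, set_a, set_b), (b, set_b, set_a)):
                for s in own:
                    if rng.random() < leakage:
                        cells[row, s] = 0
                        cells[row, rng.choice(other)] = 1
        planted.append((a, b))
    for i in range(2 * n_pairs, n_taxa):
        row = (rng.random(n_sites) < fill).astype(np.int8)
        while row.sum() == 0:
            row = (rng.random(n_sites) < fill).astype(np.int8)
        cells[i] = row
    taxa = [f"taxon_{i:02d}" for i in range(n_taxa)]
    if key is None:
        key = StratumKey(0, "LS", "bulrush", "trophic", "planted")
    return CommunityMatrix(
        key=key,
        taxa=taxa,
        sites=[f"site_{j:02d}" for j in range(n_sites)],
        cells=cells,
        cleanup_log={"planted_pairs": [[taxa[a], taxa[b]] for a, b in planted]},
    )


def generate_env(
    sites,
    n_vars: int = 8,
    focal_sites=(),
    shift: float = 0.0,
    rng: np.random.Generator | None = None,
    per_variable_shift=None,
) -> pd.DataFrame:
    """Site environmental table: iid standard normals, shifted focal sites.

    Focal sites receive ``+shift`` (standardized units) on every variable,
    or a per-variable shift vector when given.  Variable names come from
    the study's measurement vocabulary.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if shift < 0:
        raise ValueError("shift must be >= 0")
    sites = [str(s) for s in sites]
    n_vars = min(n_vars, len(ENV_VARIABLES))
    names = list(ENV_VARIABLES[:n_vars])
    data = rng.standard_normal((len(sites), n_vars))
    if per_variable_shift is None:
        per_variable_shift = np.full(n_vars, float(shift))
    else:
        per_variable_shift = np.asarray(per_variable_shift, dtype=float)
    focal = set(str(s) for s in focal_sites)
    if not focal and shift > 0:
        import logging

        logging.getLogger("coocc").warning(
            "generate_env: shift requested but focal site set is empty"
        )
    mask = np.array([s in focal for s in sites])
    data[mask] += per_variable_shift
    return pd.DataFrame(data, index=pd.Index(sites, name="site"), columns=names)


@dataclass
class StratumSpec:
    """Recipe for one synthetic stratum (one community matrix)."""

    year: int = 2011
    ecoregion: str = "LHW"
    vegetation: str = "bulrush"
    ffg: str = "predator"
    n_taxa: int = 12
    n_sites: int = 8
    fill: float = 0.45
    n_segregated_pairs: int = 0
    n_aggregated_pairs: int = 0
    env_shift: float = 0.0
    n_env_vars: int = 8
    tolerance_mode: str = "similar"  # similar | separated
    leakage: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.fill < 1:
            raise ValueError("fill must be in (0, 1)")
        if self.n_segregated_pairs + self.n_aggregated_pairs > self.n_taxa // 2:
            raise ValueError("planted pairs exceed floor(n_taxa / 2)")
        if self.tolerance_mode not in ("similar", "separated"):
            raise ValueError("tolerance_mode must be 'similar' or 'separated'")

    @property
    def key(self) -> StratumKey:
        return StratumKey(self.year, self.ecoregion, self.vegetation,
                          "trophic", self.ffg)


def default_plan(
    n_strata: int = 10,
    n_segregated_strata: int = 0,
    env_shift: float = 0.0,
    tolerance_mode: str = "similar",
) -> list[StratumSpec]:
    """A multi-stratum plan spanning years x ecoregions x zones x FFGs.

    Sizes are mid-range for the study envelope (10-16 taxa x 6-10 sites,
    fill 0.45).  The first ``n_segregated_strata`` strata carry two planted
    exclusive pairs each (plus the requested environmental shift and
    tolerance mode); the rest are null.  Planted strata are fixed at
    12 taxa x 10 sites: with fewer sites the exact two-group PERMANOVA
    cannot reach p <= 0.05 for an even split (its floor is 2/C(n, n/2),
    e.g. 0.1 at 6 sites), so habitat-shift truth would be untestable.
    """
    years = (2010, 2011, 2012)
    ecoregions = ("LHW", "LMN", "LS", "LHNE")
    zones = ("bulrush", "lily")
    ffgs = ("collector", "grazer", "predator", "shredder")
    plan = []
    for i in range(n_strata):
        planted = i < n_segregated_strata
        plan.append(
            StratumSpec(
                year=years[i % len(years)],
                ecoregion=ecoregions[(i // len(years)) % len(ecoregions)],
                vegetation=zones[i % len(zones)],
                ffg=ffgs[i % len(ffgs)],
                n_taxa=12 if planted else 10 + (i % 4) * 2,
                n_sites=10 if planted else 6 + (i % 3) * 2,
                n_segregated_pairs=2 if planted else 0,
                env_shift=env_shift if planted else 0.0,
                tolerance_mode=tolerance_mode if planted else "similar",
            )
        )
    return plan


@dataclass
class StudyData:
    """Synthetic long-format study dataset with ground truth."""

    occurrences: pd.DataFrame
    attributes: pd.DataFrame
    environment: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _simulate_stratum_matrix(spec: StratumSpec, rng: np.random.Generator):
    if spec.n_segregated_pairs > 0:
        m = plant_segregation(
            spec.n_taxa, spec.n_sites, spec.n_segregated_pairs,
            fill=spec.fill, rng=rng, leakage=spec.leakage, key=spec.key,
        )
    else:
        cells = (rng.random((spec.n_taxa, spec.n_sites)) < spec.fill).astype(np.int8)
        for i in range(spec.n_taxa):  # no empty taxa rows
            while cells[i].sum() == 0:
                cells[i] = (rng.random(spec.n_sites) < spec.fill).astype(np.int8)
        m = CommunityMatrix(
            key=spec.key,
            taxa=[f"taxon_{i:02d}" for i in range(spec.n_taxa)],
            sites=[f"site_{j:02d}" for j in range(spec.n_sites)],
            cells=cells,
        )
    if spec.n_aggregated_pairs > 0:
        # aggregated pairs: duplicate occupancy between successive free rows
        start = 2 * spec.n_segregated_pairs
        agg = []
        for p in range(spec.n_aggregated_pairs):
            a = start + 2 * p
            b = a + 1
            m.cells[b] = m.cells[a]
            agg.append([m.taxa[a], m.taxa[b]])
        m.cleanup_log["aggregated_pairs"] = agg
    return m


def generate_study(
    plan: list[StratumSpec], seed: int = 0
) -> StudyData:
    """Generate a multi-stratum occurrence/attribute/environment dataset.

    Site and taxon identifiers are made unique per stratum so each stratum
    yields exactly one community matrix per unit type.  The truth sidecar
    records, per stratum, the planted structure and the mechanism the
    pipeline is expected to recover.  Deterministic for a given seed.
    """
    occ_rows = []
    attr_rows = []
    env_frames = []
    truth: dict = {"seed": seed, "strata": []}
    families = ("Chironomidae", "Planorbidae", "Coenagrionidae", "Dytiscidae",
                "Baetidae", "Corixidae", "Leptoceridae", "Lymnaeidae")
    for idx, spec in enumerate(plan):
        rng = np.random.default_rng(derive_seed(seed, f"stratum|{idx}|{spec.key}"))
        m = _simulate_stratum_matrix(spec, rng)
        prefix = f"s{idx:02d}"
        taxa = [f"{prefix}_{t}" for t in m.taxa]
        sites = [f"{prefix}_{s}" for s in m.sites]

        for i, taxon in enumerate(taxa):
            for j, site in enumerate(sites):
                if m.cells[i, j]:
                    occ_rows.append(
                        {
                            "site": site,
                            "taxon": taxon,
                            "abundance": int(1 + rng.poisson(4)),
                            "year": spec.year,
                            "ecoregion": spec.ecoregion,
                            "vegetation": spec.vegetation,
                        }
                    )

        planted = [
            [f"{prefix}_{a}", f"{prefix}_{b}"]
            for a, b in m.cleanup_log.get("planted_pairs", [])
        ]
        planted_flat = {t for pair in planted for t in pair}
        for i, taxon in enumerate(taxa):
            if spec.tolerance_mode == "separated" and taxon in planted_flat:
                pair = next(p for p in planted if taxon in p)
                base = 1.0 if taxon == pair[0] else 8.0
            else:
                base = 5.0
            tol = float(np.clip(base + rng.normal(0, 0.5), 0, 10))
            attr_rows.append(
                {
                    "taxon": taxon,
                    "family": families[i % len(families)],
                    "ffg": spec.ffg,
                    "tolerance": round(tol, 2),
                    "overwinters": bool(rng.random() < 0.3),
                }
            )

        focal: list[str] = []
        if spec.env_shift > 0 and planted:
            a = planted[0][0]
            row = taxa.index(a)
            focal = [sites[j] for j in range(len(sites)) if m.cells[row, j]]
        env = generate_env(
            sites, n_vars=spec.n_env_vars, focal_sites=focal,
            shift=spec.env_shift, rng=rng,
        )
        env = env.reset_index().assign(year=spec.year)
        env_frames.append(env)

        if spec.n_segregated_pairs > 0:
            expected_class = "negative"
            if spec.tolerance_mode == "separated":
                expected_mech = "differential_tolerance"
            elif spec.env_shift > 0:
                expected_mech = "differential_habitat"
            else:
                expected_mech = "competitive_exclusion"
        elif spec.n_aggregated_pairs > 0:
            expected_class = "positive"
            expected_mech = None
        else:
            expected_class = "random"
            expected_mech = "neutral"
        truth["strata"].append(
            {
                "index": idx,
                "key": spec.key.to_dict(),
                "n_taxa": spec.n_taxa,
                "n_sites": spec.n_sites,
                "planted_segregated_pairs": planted,
                "focal_sites": focal,
                "env_shift": spec.env_shift,
                "tolerance_mode": spec.tolerance_mode,
                "expected_classification": expected_class,
                "expected_mechanism": expected_mech,
            }
        )

    occurrences = pd.DataFrame(occ_rows)
    attributes = pd.DataFrame(attr_rows)
    environment = pd.concat(env_frames, ignore_index=True)
    return StudyData(occurrences, attributes, environment, truth)


def write_study(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write the study tables (CSV) and truth sidecar (JSON) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "attributes": outdir / "attributes.csv",
        "environment": outdir / "environment.csv",
        "truth": outdir / "truth.json",
    }
    study.occurrences.to_csv(paths["occurrences"], index=False)
    study.attributes.to_csv(paths["attributes"], index=False)
    study.environment.to_csv(paths["environment"], index=False)
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return paths
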