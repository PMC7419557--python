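"""Multi-cohort synthetic compositional data with known ground truth.

The generator follows a logistic-normal–multinomial model: log absolute
("basis") abundances are multivariate normal with a sparse correlation matrix
Σ_c per cohort, optional additive age/sex effects on the log-mean, and
optional structural zero-inflation applied to the basis before closure.
Compositions are closed to sum 1 and observed counts are multinomial at a
stated sequencing depth. Because basis correlations are the estimand of
compositional correlation inference, every downstream stage can be scored
against the planted truth: shared edges, cohort-specific edges (an edge whose
correlation differs in exactly one cohort) and confounder loadings.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CountTable
from ._stats import spawn_seeds

SHARED = "__shared__"

#: age is sampled uniform on [20, 70) years; loadings act on (age - AGE_CENTER)
AGE_RANGE = (20.0, 70.0)
AGE_CENTER = 45.0


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study."""

    p: int
    cohorts: list[str]
    sigma_shared: np.ndarray
    sigma_cohort: dict[str, np.ndarray] = field(default_factory=dict)
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    planted_specific: list[tuple[int, int, str, float]] = field(default_factory=list)
    mu: np.ndarray | None = None
    sds: np.ndarray | None = None
    pi: np.ndarray | None = None
    zero_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    age_loading: np.ndarray | None = None
    sex_loading: np.ndarray | None = None
    features: list[str] = field(default_factory=list)

    def sigma_for(self, cohort: str) -> np.ndarray:
        return self.sigma_cohort.get(cohort, self.sigma_shared)


@dataclass
class SyntheticCohort:
    """Simulated tables for one cohort, with a pointer to the truth.

    ``log_basis`` keeps the latent pre-closure log absolute abundances so
    that recovery tests can score estimates against the generative scale.
    """

    name: str
    counts: CountTable
    abundance: AbundanceTable
    metadata: pd.DataFrame
    truth: SyntheticTruth
    log_basis: np.ndarray | None = None


def nearest_pd_correlation(
    sigma: np.ndarray, eig_floor: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result rescaled to unit
    diagonal, iterating until the smallest eigenvalue exceeds 1e-8.
    """
    s = (sigma + sigma.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(s)
        if vals.min() > 1e-8 and np.allclose(np.diag(s), 1.0, atol=1e-12):
            return s
        vals = np.clip(vals, eig_floor, None)
        s = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(s))
        s = s / np.outer(d, d)
        np.fill_diagonal(s, 1.0)
        s = (s + s.T) / 2.0
    raise RuntimeError("positive-definite correlation projection did not converge")


def make_basis_network(
    p: int,
    n_edges: int,
    rho: float,
    seed=None,
    cohorts: tuple[str, ...] = ("C1", "C2", "C3", "C4"),
) -> SyntheticTruth:
    """Random sparse basis correlation network shared by all cohorts.

    ``n_edges`` off-diagonal pairs are set to ``rho`` and the matrix is
    projected to the nearest positive-definite correlation matrix; the
    realized (post-projection) edge values are recorded as the truth.
    """
    max_edges = p * (p - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges {n_edges} exceeds p(p-1)/2 = {max_edges}")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    sigma = np.eye(p)
    iu = np.array(np.triu_indices(p, k=1)).T
    chosen = iu[rng.choice(len(iu), size=n_edges, replace=False)] if n_edges else []
    for i, j in chosen:
        sigma[i, j] = sigma[j, i] = rho
    sigma = nearest_pd_correlation(sigma)
    edges = [(int(i), int(j), float(sigma[i, j])) for i, j in chosen]
    return SyntheticTruth(
        p=p,
        cohorts=list(cohorts),
        sigma_shared=sigma,
        edges=sorted(edges),
        features=[f"s__Synth_species_{k:03d}" for k in range(p)],
    )


def plant_specific_edge(
    truth: SyntheticTruth, edge: tuple[int, int], cohort: str, rho_specific: float
) -> SyntheticTruth:
    """Plant a cohort-specific correlation on one edge of one cohort.

    The cohort's Σ is modified at ``edge`` and re-projected; the realized
    post-projection value is recorded. If re-projection perturbs any
    previously planted edge by more than 0.1 the truth would be corrupted and
    an error is raised.
    """
    i, j = sorted(int(k) for k in edge)
    if not (0 <= i < j < truth.p):
        raise ValueError(f"edge {edge} outside feature range")
    if cohort not in truth.cohorts:
        raise ValueError(f"unknown cohort {cohort!r}")
    new = copy.deepcopy(truth)
    sigma = new.sigma_for(cohort).copy()
    sigma[i, j] = sigma[j, i] = rho_specific
    sigma = nearest_pd_correlation(sigma)
    # guard previously recorded edges in this cohort
    prior = [(a, b, v) for a, b, v in new.edges] + [
        (a, b, v) for a, b, c, v in new.planted_specific if c == cohort
    ]
    for a, b, v in prior:
        if (a, b) != (i, j) and abs(sigma[a, b] - v) > 0.1:
            raise ValueError(
                f"planting {edge} in {cohort} shifted edge ({a},{b}) from "
                f"{v:.3f} to {sigma[a, b]:.3f}: truth would be corrupted"
            )
    new.sigma_cohort[cohort] = sigma
    new.planted_specific = [
        e for e in new.planted_specific if not (e[0] == i and e[1] == j and e[2] == cohort)
    ] + [(i, j, cohort, float(sigma[i, j]))]
    return new


def _default_params(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    p = truth.p
    if truth.mu is None:
        truth.mu = np.zeros(p)
    if truth.sds is None:
        # heavy-tailed spread of log abundances
        truth.sds = rng.uniform(0.5, 1.5, size=p)
    if truth.pi is None:
        truth.pi = np.zeros(p)
    if truth.age_loading is None:
        truth.age_loading = np.zeros(p)
    if truth.sex_loading is None:
        truth.sex_loading = np.zeros(p)


def simulate_cohort(
    truth: SyntheticTruth,
    cohort: str,
    n: int,
    depth: int,
    seed=None,
    age_loading: np.ndarray | None = None,
    sex_loading: np.ndarray | None = None,
) -> SyntheticCohort:
    """Draw one cohort's samples from the logistic-normal–multinomial model.

    ``age_loading``/``sex_loading`` override the truth's (shared) covariate
    loadings for this cohort, which is how cohort-specific confounding is
    planted.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    _default_params(truth, rng)
    p = truth.p
    sigma = truth.sigma_for(cohort)
    chol = np.linalg.cholesky(sigma)

    a_load = truth.age_loading if age_loading is None else np.asarray(age_loading, float)
    s_load = truth.sex_loading if sex_loading is None else np.asarray(sex_loading, float)
    age = rng.uniform(*AGE_RANGE, size=n)
    sex = rng.integers(0, 2, size=n)
    shift = (
        truth.mu[None, :]
        + np.outer(age - AGE_CENTER, a_load)
        + np.outer(sex.astype(float), s_load)
    )
    z = rng.standard_normal((n, p))
    y = shift + (z @ chol.T) * truth.sds[None, :]
    w = np.exp(y)

    # structural zeros on the basis, before closure
    keep = rng.random((n, p)) >= truth.pi[None, :]
    for i, j, pz in truth.zero_pairs:
        joint = rng.random(n) < pz
        keep[joint, i] = False
        keep[joint, j] = False
    w = w * keep
    for s in range(n):
        tries = 0
        while w[s].sum() <= 0:
            tries += 1
            if tries > 100:
                raise RuntimeError(f"sample {s}: all features zeroed after 100 retries")
            w[s] = np.exp(y[s]) * (rng.random(p) >= truth.pi)

    x = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, x[s]) for s in range(n)]).T  # p × n

    samples = [f"{cohort}_s{k:04d}" for k in range(n)]
    counts_df = pd.DataFrame(counts, index=truth.features, columns=samples)
    abund_df = counts_df / float(depth)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "cohort": cohort,
            "age": age,
            "sex": sex,
            "read_depth": depth,
        }
    ).set_index("sample", drop=False)
    return SyntheticCohort(
        name=cohort,
        counts=CountTable(data=counts_df, level="species"),
        abundance=AbundanceTable(data=abund_df, level="species"),
        metadata=meta,
        truth=truth,
        log_basis=y,
    )


_CONFIG_KEYS = {
    "cohorts",
    "p",
    "n_edges",
    "rho",
    "depth",
    "planted",
    "shared_edges",
    "pi",
    "zero_pairs",
    "age_loading",
    "sex_loading",
    "mu",
    "sds",
}


def set_shared_edges(
    truth: SyntheticTruth, edges: list[tuple[int, int, float]]
) -> SyntheticTruth:
    """Place explicit shared (all-cohort) basis correlations.

    Entries are applied to the shared Σ, the matrix re-projected to a
    positive-definite correlation, and realized values recorded.
    """
    new = copy.deepcopy(truth)
    sigma = new.sigma_shared.copy()
    for i, j, r in edges:
        i, j = sorted((int(i), int(j)))
        sigma[i, j] = sigma[j, i] = float(r)
    sigma = nearest_pd_correlation(sigma)
    new.sigma_shared = sigma
    placed = {tuple(sorted((int(i), int(j)))) for i, j, _ in edges}
    kept = [(a, b, v) for a, b, v in new.edges if (a, b) not in placed]
    new.edges = sorted(
        kept + [(a, b, float(sigma[a, b])) for a, b in placed]
    )
    return new


def default_config() -> dict:
    """Study conditions used throughout: 4 cohorts of 300 samples, 30
    features, 12 shared edges at ρ=0.6, depth 50,000, no zero inflation."""
    return {
        "cohorts": [{"name": c, "n": 300} for c in ("C1", "C2", "C3", "C4")],
        "p": 30,
        "n_edges": 12,
        "rho": 0.6,
        "depth": 50_000,
    }


def _validate_config(config: dict) -> None:
    bad = sorted(set(config) - _CONFIG_KEYS)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    missing = [k for k in ("cohorts", "p") if k not in config]
    if missing:
        raise ValueError(f"missing config keys: {missing}")
    for c in config["cohorts"]:
        if "name" not in c or "n" not in c:
            raise ValueError(f"cohort entries need 'name' and 'n': {c}")
    if not 2 <= len(config["cohorts"]) <= 4:
        raise ValueError("between 2 and 4 cohorts are supported")


def make_study(config: dict | None = None, seed=None) -> dict[str, SyntheticCohort]:
    """Generate a full multi-cohort study from a config mapping.

    Deterministic given ``seed``: the master seed is expanded into child
    seeds (basis network, then one per cohort) via numpy's SeedSequence.
    """
    config = {**default_config(), **(config or {})}
    _validate_config(config)
    names = [c["name"] for c in config["cohorts"]]
    p = int(config["p"])
    seeds = spawn_seeds(seed, 2 + len(names))

    truth = make_basis_network(
        p,
        int(config.get("n_edges", 0)),
        float(config.get("rho", 0.0)),
        seed=seeds[0],
        cohorts=tuple(names),
    )
    rng = np.random.default_rng(seeds[1])
    for key in ("mu", "sds", "pi", "age_loading", "sex_loading"):
        if key in config:
            val = config[key]
            arr = np.full(p, float(val)) if np.isscalar(val) else np.asarray(val, float)
            if arr.shape != (p,):
                raise ValueError(f"config {key!r} must be scalar or length-{p}")
            setattr(truth, key, arr)
    _default_params(truth, rng)
    truth.zero_pairs = [
        (int(i), int(j), float(pz)) for i, j, pz in config.get("zero_pairs", [])
    ]
    if config.get("shared_edges"):
        truth = set_shared_edges(
            truth, [(e["i"], e["j"], e["rho"]) for e in config["shared_edges"]]
        )
    for spec in config.get("planted", []):
        truth = plant_specific_edge(
            truth, (spec["i"], spec["j"]), spec["cohort"], spec["rho"]
        )

    study = {}
    for k, c in enumerate(config["cohorts"]):
        depth = int(c.get("depth", config.get("depth", 50_000)))
        overrides = {}
        for key in ("age_loading", "sex_loading"):
            if key in c:
                val = c[key]
                overrides[key] = (
                    np.full(p, float(val)) if np.isscalar(val) else np.asarray(val, float)
                )
        study[c["name"]] = simulate_cohort(
            truth, c["name"], int(c["n"]), depth, seed=seeds[2 + k], **overrides
        )
    return study


def write_study(study: dict[str, SyntheticCohort], outdir) -> None:
    """Write per-cohort abundance/count TSVs and a combined metadata TSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    metas = []
    for name, cohort in study.items():
        cohort.abundance.data.to_csv(out / f"{name}_abundance.tsv", sep="\t")
        cohort.counts.data.to_csv(out / f"{name}_counts.tsv", sep="\t")
        metas.append(cohort.metadata)
    pd.concat(metas).to_csv(out / "metadata.tsv", sep="\t", index=False)
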