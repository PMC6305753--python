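"""Synthetic microbial-community data with phylogenetically clustered signals.

The generator emulates a targeted-sequencing experiment: a random coalescent
tree over p OTUs; Dirichlet-multinomial (DM) counts with library sizes drawn
from a negative binomial (mean 5,000, dispersion 25 — a typical sequencing
depth); OTU proportions obtained by dividing each sample's counts by its
total.  Outcome-associated OTUs ("aOTUs") are chosen relative to a PAM
partition of the OTUs into clusters on patristic distances, under four
scenarios:

* S1 — tree informative: 12 aOTUs from a single cluster, equal effect sizes,
  same direction.
* S2 — tree informative: as S1 with heterogeneous effect magnitudes.
* S3 — tree non-informative: 12 aOTUs in 12 distinct clusters (at most one
  per cluster).
* S4 — tree non-informative: as S1 with the effect direction reversed for
  half of the aOTUs.

The outcome is built from the linear predictor eta_i = beta0 + sum_{j in A}
beta_j x_ij on the OTU proportions.  Continuous outcomes add Gaussian noise
with sigma calibrated so the signal strength sd(eta)/sigma equals the
requested level (levels 1.0 / 1.5 / 2.0 for weak / medium / strong); binary
outcomes are Bernoulli draws from the logistic probability with beta scaled
so sum_{j in A} var(x_j) beta_j^2 equals the requested level (5 / 10 / 20),
sampled case-control from a large pool.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .phylo import PatristicDistanceMatrix, patristic_distances

__all__ = [
    "DMParams",
    "ScenarioSpec",
    "SimulatedDataset",
    "default_dm_params",
    "simulate_tree",
    "estimate_dm_params",
    "sample_counts",
    "pam_partition",
    "designate_aotus",
    "generate_outcome",
    "make_dataset",
    "SIGNAL_LEVELS",
]

#: Named signal levels (weak / medium / strong) by family.
SIGNAL_LEVELS = {
    "linear": {"S": 1.0, "M": 1.5, "L": 2.0},
    "logistic": {"S": 5.0, "M": 10.0, "L": 20.0},
}


@dataclass
class DMParams:
    """Dirichlet-multinomial parameters plus the library-size model.

    ``dispersion`` is the DM overdispersion theta in (0, 1); the Dirichlet
    concentration is ``proportions * (1 - theta) / theta``.  Library sizes
    are negative binomial with the given mean and dispersion (size)
    parameter.
    """

    proportions: np.ndarray
    dispersion: float
    depth_mean: float = 5000.0
    depth_dispersion: float = 25.0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-10:
            raise ValueError("mean proportions must sum to 1")
        if not (0 < self.dispersion < 1):
            raise ValueError("DM dispersion must lie in (0, 1)")


def default_dm_params(p: int = 200, seed: int = 0) -> DMParams:
    """Default mean-proportion profile: log-normal (log-sd 1.5), theta 0.02.

    A log-normal abundance profile reproduces the skewness of real
    communities — a few dominant OTUs and a long tail of rare ones.  Users
    with real count data should prefer :func:`estimate_dm_params`.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=1.5, size=p)
    pi = raw / raw.sum()
    return DMParams(proportions=pi, dispersion=0.02)


def simulate_tree(p: int, seed: int = 0) -> dendropy.Tree:
    """Random coalescent tree with p leaves (exponential waiting times).

    Leaves are labeled ``OTU1 ... OTUp``.  Coalescent trees are ultrametric:
    every leaf sits at the same distance from the root.
    """
    if p < 2:
        raise ValueError("need at least 2 leaves")
    tns = dendropy.TaxonNamespace([f"OTU{i + 1}" for i in range(p)])
    tree = treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )
    return tree


def estimate_dm_params(counts: np.ndarray) -> DMParams:
    """Method-of-moments DM estimates from a count table (samples x OTUs).

    Mean proportions come from pooled relative abundances.  The dispersion
    uses the moment identity for the variance of observed proportions,
    Var(p_ij) = pi_j (1 - pi_j) (E[1/N_i] + theta (1 - E[1/N_i])), aggregated
    over OTUs.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 OTUs")
    depths = counts.sum(axis=1)
    if np.any(depths <= 0):
        raise ValueError("every sample must have a positive total count")
    pi = counts.sum(axis=0) / counts.sum()
    if np.all(counts.sum() == 0):
        raise ValueError("all-zero count table")
    props = counts / depths[:, None]
    s2 = props.var(axis=0, ddof=1)
    v = pi * (1.0 - pi)
    a = float(np.mean(1.0 / depths))
    theta = (s2.sum() - a * v.sum()) / ((1.0 - a) * v.sum())
    theta = float(np.clip(theta, 1e-8, 1 - 1e-8))
    depth_mean = float(depths.mean())
    dvar = float(depths.var(ddof=1))
    # NB: var = m + m^2 / size
    size = depth_mean**2 / (dvar - depth_mean) if dvar > depth_mean else 1e6
    return DMParams(proportions=pi / pi.sum(), dispersion=theta,
                    depth_mean=depth_mean, depth_dispersion=float(size))


def sample_counts(params: DMParams, n: int, seed: int = 0):
    """Draw n samples of DM counts; returns (counts, proportions).

    Per sample: library size ~ NB(mean, dispersion); composition ~
    Dirichlet(pi (1 - theta) / theta); counts ~ Multinomial(size,
    composition); proportions are counts over the sample total.
    """
    rng = np.random.default_rng(seed)
    p = params.proportions.size
    m, k = params.depth_mean, params.depth_dispersion
    depths = rng.negative_binomial(n=k, p=k / (k + m), size=n)
    depths = np.maximum(depths, 1)  # guard: a zero-depth sample is unusable
    conc = params.proportions * (1.0 - params.dispersion) / params.dispersion
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        comp = rng.dirichlet(conc)
        counts[i] = rng.multinomial(depths[i], comp)
    proportions = counts / counts.sum(axis=1, keepdims=True)
    return counts, proportions


def _pam_total_cost(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam_partition(D, k: int, seed: int = 0) -> np.ndarray:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Returns integer cluster labels (0..k-1) aligned to the matrix order.
    The algorithm is deterministic given the input order; ``seed`` is kept in
    the signature for interface stability.
    """
    Dm = D.D if isinstance(D, PatristicDistanceMatrix) else np.asarray(D, dtype=float)
    p = Dm.shape[0]
    if k > p:
        raise ValueError(f"k={k} exceeds number of points p={p}")
    if k < 1:
        raise ValueError("k must be >= 1")

    # BUILD: greedy cost minimization
    medoids = [int(np.argmin(Dm.sum(axis=1)))]
    while len(medoids) < k:
        cur = Dm[:, medoids].min(axis=1)
        gains = np.sum(np.minimum(Dm, cur[None, :]), axis=1)
        gains[medoids] = np.inf
        medoids.append(int(np.argmin(gains)))
    medoids = np.array(sorted(medoids))

    # SWAP: best-improvement until no swap lowers the total cost
    cost = _pam_total_cost(Dm, medoids)
    improved = True
    while improved:
        improved = False
        best = (cost, None)
        in_medoids = np.zeros(p, dtype=bool)
        in_medoids[medoids] = True
        candidates = np.flatnonzero(~in_medoids)
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            base = (Dm[:, others].min(axis=1) if others.size
                    else np.full(p, np.inf))
            for h in candidates:
                new_cost = float(np.minimum(base, Dm[:, h]).sum())
                if new_cost < best[0] - 1e-12:
                    best = (new_cost, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids = medoids.copy()
            medoids[mi] = h
            medoids = np.sort(medoids)
            cost = best[0]
            improved = True

    labels = np.argmin(Dm[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # each medoid belongs to its own cluster
    return labels


@dataclass
class ScenarioSpec:
    """One simulation condition.

    Defaults follow the study design: 200 OTUs in 20 PAM clusters, 12 aOTUs;
    continuous outcomes use 100 training and 200 testing samples; binary
    outcomes use 50 cases + 50 controls for training and 100 + 100 for
    testing.  ``signal`` may be a named level ("S"/"M"/"L") or a number.
    """

    scenario: str = "S1"
    signal: float | str = "L"
    family: str = "linear"
    n_train: int | None = None
    n_test: int | None = None
    p: int = 200
    n_clusters: int = 20
    n_aotu: int = 12
    seed: int = 0
    dm_params: DMParams | None = None
    signal_definition: str = "sd"   # continuous: "sd" -> sd(eta)/sigma; "var" -> var(eta)/sigma

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2", "S3", "S4"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_train is None:
            self.n_train = 100
        if self.n_test is None:
            self.n_test = 200

    @property
    def signal_value(self) -> float:
        if isinstance(self.signal, str):
            return SIGNAL_LEVELS[self.family][self.signal]
        return float(self.signal)


@dataclass
class SimulatedDataset:
    """A complete simulated study with its generating truth."""

    spec: ScenarioSpec
    tree: dendropy.Tree
    distances: PatristicDistanceMatrix
    cluster_labels: np.ndarray
    counts_train: np.ndarray
    counts_test: np.ndarray
    x_train: np.ndarray           # proportions, samples x OTUs
    x_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    A: np.ndarray                 # indices of truly associated OTUs
    beta_true: np.ndarray
    beta0: float
    sigma_eps: float              # continuous only; nan for binary
    realized_signal: float
    otu_ids: list[str] = field(default_factory=list)


def designate_aotus(cluster_labels: np.ndarray, scenario: str,
                    n_aotu: int = 12, seed: int = 0):
    """Choose the associated OTUs and their sign/magnitude pattern.

    Returns ``(A, signs, magnitudes)``; magnitudes are pre-calibration
    (later rescaled to hit the requested signal strength).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(cluster_labels)
    if scenario in ("S1", "S2", "S4"):
        sizes = np.bincount(labels)
        eligible = np.flatnonzero(sizes >= n_aotu)
        if eligible.size == 0:
            raise ValueError(
                f"no cluster has >= {n_aotu} members (sizes: {sorted(sizes)}); "
                "cannot form an associated cluster"
            )
        # the cluster whose size is closest to n_aotu from above
        chosen = eligible[np.argmin(sizes[eligible])]
        members = np.flatnonzero(labels == chosen)
        A = np.sort(rng.choice(members, size=n_aotu, replace=False))
        signs = np.ones(n_aotu)
        if scenario == "S4":
            flip = rng.choice(n_aotu, size=n_aotu // 2, replace=False)
            signs[flip] = -1.0
        if scenario == "S2":
            mags = rng.uniform(0.5, 1.5, size=n_aotu)
        else:
            mags = np.ones(n_aotu)
    elif scenario == "S3":
        k = labels.max() + 1
        if k < n_aotu:
            raise ValueError(
                f"S3 needs at least {n_aotu} clusters, got {k}"
            )
        chosen_clusters = rng.choice(k, size=n_aotu, replace=False)
        A = np.sort(np.array([
            int(rng.choice(np.flatnonzero(labels == c)))
            for c in chosen_clusters
        ]))
        signs = np.ones(n_aotu)
        mags = np.ones(n_aotu)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return A, signs, mags


def generate_outcome(x: np.ndarray, A: np.ndarray, signs: np.ndarray,
                     mags: np.ndarray, spec: ScenarioSpec, seed: int = 0,
                     x_extra: np.ndarray | None = None):
    """Build the outcome from the linear predictor on the aOTU proportions.

    Continuous: ``y = eta + eps`` with sigma_eps calibrated on ``x`` so the
    realized signal strength equals the request exactly.  Binary: beta is
    scaled so the variance-weighted coefficient norm equals the request; the
    returned y corresponds to the rows of ``x`` (with ``x_extra`` rows
    appended if given).

    Returns ``(y, beta_true, beta0, sigma_eps, realized_signal)``.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    p = x.shape[1]
    beta = np.zeros(p)
    beta[A] = signs * mags
    level = spec.signal_value

    X_all = x if x_extra is None else np.vstack([x, np.asarray(x_extra, float)])
    eta_base = X_all @ beta
    sd_eta = float(eta_base[: x.shape[0]].std())
    if sd_eta == 0:
        raise ValueError("linear predictor has zero variance: aOTUs absent")

    if spec.family == "linear":
        if spec.signal_definition == "sd":
            sigma = sd_eta / level
        elif spec.signal_definition == "var":
            sigma = float(eta_base[: x.shape[0]].var()) / level
        else:
            raise ValueError(f"unknown signal definition {spec.signal_definition!r}")
        beta0 = 0.0
        eta = beta0 + eta_base
        y = eta + rng.normal(0.0, sigma, size=eta.size)
        realized = sd_eta / sigma if spec.signal_definition == "sd" else \
            float(eta_base[: x.shape[0]].var()) / sigma
        return y, beta, beta0, sigma, float(realized)

    # binary: scale beta so sum_A var(x_j) beta_j^2 == level, var on the
    # calibration design (the pool, when x is the pool)
    var_x = X_all[: x.shape[0]].var(axis=0)
    base = float(np.sum(var_x[A] * beta[A] ** 2))
    if base == 0:
        raise ValueError("aOTU abundances have zero variance")
    beta = beta * np.sqrt(level / base)
    eta_base = X_all @ beta
    beta0 = -float(eta_base[: x.shape[0]].mean())
    eta = beta0 + eta_base
    pi = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, pi).astype(float)
    realized = float(np.sum(var_x[A] * beta[A] ** 2))
    return y, beta, beta0, float("nan"), realized


def make_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """End-to-end generation of one simulated study (fully seeded)."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    tree = simulate_tree(spec.p, seed=int(seeds[0]))
    D = patristic_distances(tree)
    labels = pam_partition(D, spec.n_clusters, seed=int(seeds[1]))
    A, signs, mags = designate_aotus(labels, spec.scenario, spec.n_aotu,
                                     seed=int(seeds[2]))
    params = spec.dm_params or default_dm_params(spec.p, seed=int(seeds[3]))

    if spec.family == "linear":
        n_tot = spec.n_train + spec.n_test
        counts, props = sample_counts(params, n_tot, seed=int(seeds[4]))
        y, beta, beta0, sigma, realized = generate_outcome(
            props[: spec.n_train], A, signs, mags, spec, seed=int(seeds[5]),
            x_extra=props[spec.n_train:],
        )
        tr = slice(0, spec.n_train)
        te = slice(spec.n_train, n_tot)
        ds = SimulatedDataset(
            spec=spec, tree=tree, distances=D, cluster_labels=labels,
            counts_train=counts[tr], counts_test=counts[te],
            x_train=props[tr], x_test=props[te],
            y_train=y[: spec.n_train], y_test=y[spec.n_train:],
            A=A, beta_true=beta, beta0=beta0, sigma_eps=sigma,
            realized_signal=realized, otu_ids=list(D.labels),
        )
        return ds

    # binary: draw a pool 20x the needed size, generate labels on the pool,
    # then sample balanced cases/controls without replacement
    n_cases_tr = spec.n_train // 2
    n_ctrl_tr = spec.n_train - n_cases_tr
    n_cases_te = spec.n_test // 2
    n_ctrl_te = spec.n_test - n_cases_te
    need = spec.n_train + spec.n_test
    pool_n = 20 * need
    counts, props = sample_counts(params, pool_n, seed=int(seeds[4]))
    y, beta, beta0, sigma, realized = generate_outcome(
        props, A, signs, mags, spec, seed=int(seeds[5])
    )
    rng2 = np.random.default_rng(int(seeds[5]) + 1)
    cases = np.flatnonzero(y == 1)
    ctrls = np.flatnonzero(y == 0)
    if cases.size < n_cases_tr + n_cases_te or ctrls.size < n_ctrl_tr + n_ctrl_te:
        raise ValueError(
            f"pool of {pool_n} yielded {cases.size} cases / {ctrls.size} "
            "controls; not enough for the requested case-control design"
        )
    cases = rng2.permutation(cases)
    ctrls = rng2.permutation(ctrls)
    tr_idx = np.concatenate([cases[:n_cases_tr], ctrls[:n_ctrl_tr]])
    te_idx = np.concatenate([cases[n_cases_tr:n_cases_tr + n_cases_te],
                             ctrls[n_ctrl_tr:n_ctrl_tr + n_ctrl_te]])
    tr_idx = rng2.permutation(tr_idx)
    te_idx = rng2.permutation(te_idx)
    return SimulatedDataset(
        spec=spec, tree=tree, distances=D, cluster_labels=labels,
        counts_train=counts[tr_idx], counts_test=counts[te_idx],
        x_train=props[tr_idx], x_test=props[te_idx],
        y_train=y[tr_idx], y_test=y[te_idx],
        A=A, beta_true=beta, beta0=beta0, sigma_eps=float("nan"),
        realized_signal=realized, otu_ids=list(D.labels),
    )
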