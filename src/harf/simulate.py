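"""Biologically inspired two-class synthetic cohorts.

The generator emulates a target-inhibition view of drug response: each cell
line's proliferation is driven by a small set of kinases phi (at most
``max_targets`` drawn from a pool of ``n_targets_pool``), and a drug is
described by its normalized inhibition profile over the pool (values in
[0, 1]). The sensitivity of a cell line is

    sensitivity = b * min over shared kinases of the drug's inhibition,

with b ~ unif(0, 1) an independent per-cell-line attenuation; if the drug
inhibits none of the line's kinases the sensitivity is 0. Heterogeneity
enters through class-biased target selection: type-1 lines draw kinase
indices from a left-truncated N(0, 1) on [0, inf) (low indices), type-2
lines from a right-truncated N(9, 1) on (-inf, 9] (high indices). With the
default drug profile -- full inhibition of the low-index half of the pool,
decaying to 0.5 at the top index -- type 1 is the sensitive class.

Because b is uniform on (0, 1), the achievable class-mean sensitivity is
capped at E[b] = 0.5 no matter the profile; the default profile places the
two class means at roughly 0.5 and 0.25 and, just as importantly, separates
them cleanly.

Expression for ``n_genes`` genes is simulated microarray-style: a per-gene
baseline drawn from a scaled beta distribution and shared by all samples,
class-specific shifts of +/- N(shift_mean, shift_sd^2) on small marker-gene
sets (an up-set in class 1 and, by default, a disjoint down-set in class 2,
leaving the remaining genes class-neutral), and i.i.d. N(0, noise_sd^2)
measurement noise on every entry. The expression is informative about the
class only -- within a class it is independent of the response, so a
regressor can do no better than the class-conditional mean response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from .data_io import Dataset, dataset_from_arrays

__all__ = [
    "SimulationConfig",
    "default_drug_profile",
    "draw_targets",
    "sensitivity",
    "simulate_expression",
    "make_dataset",
]


def default_drug_profile(pool_size: int = 10) -> np.ndarray:
    """Inhibition 1.0 on the low-index half, decaying linearly to 0.5."""
    half = pool_size // 2
    rest = pool_size - half
    tail = 1.0 - 0.5 * np.arange(1, rest + 1) / rest
    return np.concatenate([np.ones(half), tail])


@dataclass
class SimulationConfig:
    """All knobs of the two-class cohort generator.

    ``drug_inhibition`` may be a length-``n_targets_pool`` vector (one drug)
    or an (r, n_targets_pool) matrix for a multivariate cohort of r drugs.
    ``class_mean_targets`` optionally rescales each class's responses to hit
    prescribed class means (used for class-imbalance experiments where the
    response distributions, not the pathway model, are the object of study).
    """

    n_targets_pool: int = 10
    max_targets: int = 5
    class1_target_loc: float = 0.0     # left-truncated N(loc, 1) on [loc, inf)
    class2_target_loc: float = 9.0     # right-truncated N(loc, 1) on (-inf, loc]
    target_scale: float = 1.0
    draw_cap: int = 25                 # truncated-normal draws before giving up
    drug_inhibition: np.ndarray | None = None
    n_genes: int = 100
    n_marker_genes: int = 10
    shift_mean: float = 1.25
    shift_sd: float = 0.5
    noise_sd: float = 0.4
    base_expr_shape: tuple = (2.0, 2.0)
    base_expr_scale: float = 10.0
    down_set: str = "disjoint"         # or "all_remaining" (every non-marker gene)
    n_per_class: tuple = (25, 25)
    class_mean_targets: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug_inhibition is None:
            self.drug_inhibition = default_drug_profile(self.n_targets_pool)
        self.drug_inhibition = np.atleast_2d(np.asarray(self.drug_inhibition, dtype=float))
        if self.drug_inhibition.shape[1] != self.n_targets_pool:
            raise ValueError("drug_inhibition must have one value per pool kinase")
        if not ((self.drug_inhibition >= 0) & (self.drug_inhibition <= 1)).all():
            raise ValueError("inhibition values must lie in [0, 1]")
        if not 1 <= self.max_targets <= self.n_targets_pool:
            raise ValueError("max_targets must lie in 1..n_targets_pool")
        for name in ("shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.down_set not in ("disjoint", "all_remaining"):
            raise ValueError("down_set must be 'disjoint' or 'all_remaining'")
        if self.down_set == "disjoint" and 2 * self.n_marker_genes > self.n_genes:
            raise ValueError("disjoint marker sets need n_genes >= 2*n_marker_genes")

    @property
    def n_drugs(self) -> int:
        return self.drug_inhibition.shape[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_inhibition"] = self.drug_inhibition.tolist()
        return d


def draw_targets(config: SimulationConfig, class_id: int, rng) -> np.ndarray:
    """Draw a cell line's kinase set phi with class-biased indices.

    Continuous truncated-normal draws are mapped to pool indices by flooring
    toward the truncation boundary (floor for the class-1 law supported on
    [0, inf), ceiling for the class-2 law supported on (-inf, 9]) and
    clipping to the pool, which keeps the discrete mode at the boundary
    index just as the continuous densities peak there. Drawing repeats until
    ``max_targets`` distinct indices are collected or ``draw_cap`` draws
    have been spent, so phi has between 1 and max_targets members.
    """
    if class_id == 1:
        loc, a, b = config.class1_target_loc, 0.0, np.inf
    elif class_id == 2:
        loc, a, b = config.class2_target_loc, -np.inf, 0.0
    else:
        raise ValueError("class_id must be 1 or 2")
    dist = truncnorm(a, b, loc=loc, scale=config.target_scale)
    draws = dist.rvs(size=config.draw_cap, random_state=rng)
    mapped = np.floor(draws) if class_id == 1 else np.ceil(draws)
    idx = np.clip(mapped.astype(int), 0, config.n_targets_pool - 1)
    chosen: list[int] = []
    for i in idx:
        if i not in chosen:
            chosen.append(int(i))
        if len(chosen) == config.max_targets:
            break
    return np.array(chosen, dtype=int)


def sensitivity(config: SimulationConfig, targets, rng, b=None, drug: int = 0) -> float:
    """b * min inhibition over the kinases shared by the drug and the line.

    Kinases with zero inhibition are not drug targets; an empty intersection
    yields sensitivity 0. ``b`` overrides the unif(0, 1) draw (test hook).
    Even when the intersection is empty the uniform draw is consumed, so the
    random stream does not depend on the data.
    """
    targets = np.asarray(targets, dtype=int)
    if targets.size == 0:
        raise ValueError("a cell line needs at least one kinase")
    drawn = rng.uniform(0.0, 1.0) if b is None else float(b)
    profile = config.drug_inhibition[drug]
    shared = profile[targets]
    shared = shared[shared > 0.0]
    if shared.size == 0:
        return 0.0
    return drawn * float(shared.min())


def _marker_sets(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    up = np.arange(config.n_marker_genes)
    if config.down_set == "disjoint":
        down = np.arange(config.n_marker_genes, 2 * config.n_marker_genes)
    else:
        down = np.arange(config.n_marker_genes, config.n_genes)
    return up, down


def simulate_expression(config: SimulationConfig, class_ids, rng) -> np.ndarray:
    """Simulated expression matrix (n_samples, n_genes).

    Baseline per gene ~ beta(a, b) * scale, shared across samples; class-1
    rows add N(shift_mean, shift_sd^2) on the up-marker genes; class-2 rows
    subtract the same law on the down set; all entries get N(0, noise_sd^2).
    """
    class_ids = np.asarray(class_ids, dtype=int)
    n = class_ids.size
    a, b = config.base_expr_shape
    base = rng.beta(a, b, size=config.n_genes) * config.base_expr_scale
    X = np.tile(base, (n, 1))
    up, down = _marker_sets(config)
    rows1 = np.flatnonzero(class_ids == 1)
    rows2 = np.flatnonzero(class_ids == 2)
    if up.size and rows1.size:
        X[np.ix_(rows1, up)] += rng.normal(config.shift_mean, config.shift_sd,
                                           size=(rows1.size, up.size))
    if down.size and rows2.size:
        X[np.ix_(rows2, down)] -= rng.normal(config.shift_mean, config.shift_sd,
                                             size=(rows2.size, down.size))
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)
    return X


def make_dataset(config: SimulationConfig) -> Dataset:
    """Full cohort: targets -> sensitivities -> expression -> aligned Dataset.

    Empty classes (a zero in ``n_per_class``) are dropped from the label
    coding, so a (0, 25) cohort loads as a single-category dataset.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_class
    class_ids = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    if class_ids.size == 0:
        raise ValueError("n_per_class sums to zero")

    responses = np.zeros((class_ids.size, config.n_drugs))
    for i, cls in enumerate(class_ids):
        phi = draw_targets(config, int(cls), rng)
        for d in range(config.n_drugs):
            responses[i, d] = sensitivity(config, phi, rng, drug=d)

    if config.class_mean_targets is not None:
        for cls, target_mean in zip((1, 2), config.class_mean_targets):
            rows = class_ids == cls
            if not rows.any():
                continue
            for d in range(config.n_drugs):
                current = responses[rows, d].mean()
                if current > 0:
                    responses[rows, d] *= target_mean / current

    X = simulate_expression(config, class_ids, rng)

    keep_names = [name for name, count in (("type1", n1), ("type2", n2)) if count > 0]
    labels = np.array([f"type{c}" for c in class_ids])
    sample_ids = [f"c{c}_s{i:03d}" for i, c in enumerate(class_ids)]
    feature_ids = [f"g{j:03d}" for j in range(config.n_genes)]
    ds = dataset_from_arrays(X, responses, labels, sample_ids=sample_ids,
                             feature_ids=feature_ids)
    assert ds.label_names == keep_names
    return ds
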