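"""Synthetic paired control/treated fractionation datasets with known truth.

Profiles are drawn from Dirichlet distributions concentrated around
organelle-specific compositional centroids, which reproduces the essential
structure of sum-normalized reporter-ion profiles: well-separated marker
clusters, replicate-to-replicate noise, and a configurable set of proteins
whose compartment differs between the two conditions ("movers").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spatial_data import DEFAULT_CLASSES, FractionationExperiment, MarkerMap

#: Default per-class marker counts (11 compartments, 548 markers total).
DEFAULT_MARKER_COUNTS: tuple[int, ...] = (58, 96, 29, 16, 17, 101, 107, 32, 47, 15, 30)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the paired-dataset generator.

    ``mover_completeness`` interpolates a mover's treated-condition centroid
    between its old (0) and new (1) compartment.  ``concentration`` is the
    Dirichlet precision: larger values give tighter profiles.
    """

    n_classes: int = 11
    n_fractions: int = 10
    n_replicates: int = 3
    markers_per_class: tuple[int, ...] = DEFAULT_MARKER_COUNTS
    n_unknown: int = 500
    n_movers: int = 0
    mover_completeness: float = 1.0
    concentration: float = 200.0
    separation: float = 0.3
    mixture_fraction: float = 0.2
    mover_min_peak_distance: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 compartment classes")
        if len(self.markers_per_class) != self.n_classes:
            raise ConfigError("markers_per_class length must equal n_classes")
        if self.n_movers > self.n_unknown:
            raise ConfigError("n_movers cannot exceed n_unknown")
        if not 0.0 <= self.mover_completeness <= 1.0:
            raise ConfigError("mover_completeness must lie in [0, 1]")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ConfigError("mixture_fraction must lie in [0, 1]")

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.n_classes == len(DEFAULT_CLASSES):
            return DEFAULT_CLASSES
        return tuple(f"class_{i + 1:02d}" for i in range(self.n_classes))


@dataclass
class GroundTruth:
    """True compartments and mover set backing a simulated dataset."""

    true_class_control: dict[str, str]
    true_class_treated: dict[str, str]
    mover_ids: frozenset[str]
    mover_pairs: dict[str, tuple[str, str]]
    marker_classes: dict[str, str]
    mixture_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.mover_pairs) != set(self.mover_ids):
            raise ConfigError("mover_pairs keys must equal mover_ids")
        for pid, cls in self.true_class_control.items():
            if pid not in self.mover_ids and self.true_class_treated[pid] != cls:
                raise ConfigError(f"non-mover {pid!r} changes class between conditions")

    def marker_map(self) -> MarkerMap:
        return MarkerMap(dict(self.marker_classes))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": pid,
                "class_control": self.true_class_control[pid],
                "class_treated": self.true_class_treated[pid],
                "is_marker": pid in self.marker_classes,
                "is_mover": pid in self.mover_ids,
                "is_mixture": pid in self.mixture_ids,
            }
            for pid in sorted(self.true_class_control)
        ]
        return pd.DataFrame(rows)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two compositions."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def make_class_centroids(
    n_classes: int,
    n_fractions: int,
    seed: int,
    separation: float = 0.3,
    max_retries: int = 50,
) -> np.ndarray:
    """Build ``n_classes`` compositional centroids over ``n_fractions`` parts.

    Each centroid is a (possibly bimodal) Gaussian bump over fraction index,
    lightly jittered; centroid sets are re-drawn until every pairwise
    total-variation distance reaches ``separation``.

    Returns an array of shape ``(n_classes, n_fractions)`` whose rows sum
    to one.  Deterministic for a fixed seed.
    """
    if n_classes > 2 * n_fractions:
        raise ConfigError("n_classes must not exceed 2 * n_fractions")
    rng = np.random.default_rng(seed)
    grid = np.arange(n_fractions, dtype=float)
    for _ in range(max_retries):
        centroids = np.empty((n_classes, n_fractions))
        for k in range(n_classes):
            if k < n_fractions:
                base = np.exp(-((grid - k) ** 2) / (2 * 0.5**2))
            else:
                # second cycle: broad plateaus at staggered half-integer
                # centres, so peak-fraction sets stay distinct from the
                # sharp single-peak classes
                centre = ((k - n_fractions) * 2.5 + 4.5) % n_fractions
                base = np.exp(-((grid - centre) ** 2) / (2 * 1.2**2))
            base = base * np.exp(0.05 * rng.standard_normal(n_fractions))
            bump = base / base.sum()
            # background: reporter channels never read zero (near-zero
            # Dirichlet concentrations would make log-ratio noise heavy
            # tailed), and the final supernatant carries extra soluble
            # material, which also stabilizes it as the ALR reference
            background = np.full(n_fractions, 0.25 / n_fractions)
            background[-1] += 0.10
            centroids[k] = 0.65 * bump + background
        min_tv = min(
            total_variation(centroids[i], centroids[j])
            for i in range(n_classes)
            for j in range(i + 1, n_classes)
        )
        if min_tv >= separation:
            return centroids
    raise ConfigError(
        f"could not reach pairwise separation {separation} after {max_retries} tries"
    )


def _floor_composition(profile: np.ndarray, floor: float = 1e-9) -> np.ndarray:
    """Clip exact zeros produced by Dirichlet draws and renormalize."""
    clipped = np.maximum(profile, floor)
    return clipped / clipped.sum()


def simulate_dataset(
    config: GeneratorConfig,
) -> tuple[FractionationExperiment, FractionationExperiment, GroundTruth]:
    """Simulate paired control/treated experiments plus ground truth.

    Marker proteins (``M####``) sit at pure class centroids in both
    conditions.  Unknown proteins (``P####``) are sampled 80/20 from pure
    classes and two-class mixtures; movers are drawn from the pure unknowns
    and switch to a different class in the treated condition, with centroid
    ``lam * new + (1 - lam) * old`` where ``lam`` is ``mover_completeness``.
    """
    rng = np.random.default_rng(config.seed)
    centroids = make_class_centroids(
        config.n_classes, config.n_fractions, config.seed, config.separation
    )
    names = config.class_names

    marker_ids: list[str] = []
    marker_classes: dict[str, str] = {}
    i = 0
    for cls_idx, count in enumerate(config.markers_per_class):
        for _ in range(count):
            pid = f"M{i:04d}"
            marker_ids.append(pid)
            marker_classes[pid] = names[cls_idx]
            i += 1

    unknown_ids = [f"P{i:04d}" for i in range(config.n_unknown)]
    n_mix = int(round(config.mixture_fraction * config.n_unknown))
    mixture_ids = (
        {str(p) for p in rng.choice(unknown_ids, size=n_mix, replace=False)} if n_mix else set()
    )
    pure_unknowns = [p for p in unknown_ids if p not in mixture_ids]
    if config.n_movers > len(pure_unknowns):
        raise ConfigError("not enough pure unknown proteins to host all movers")
    mover_ids = (
        {str(p) for p in rng.choice(pure_unknowns, size=config.n_movers, replace=False)}
        if config.n_movers
        else set()
    )

    # per-protein control-condition centroid + class bookkeeping
    control_centroid: dict[str, np.ndarray] = {}
    treated_centroid: dict[str, np.ndarray] = {}
    true_ctrl: dict[str, str] = {}
    true_trt: dict[str, str] = {}
    mover_pairs: dict[str, tuple[str, str]] = {}

    for pid in marker_ids:
        k = names.index(marker_classes[pid])
        control_centroid[pid] = centroids[k]
        treated_centroid[pid] = centroids[k]
        true_ctrl[pid] = names[k]
        true_trt[pid] = names[k]

    # movers translocate between spatially resolved compartments: target
    # classes whose centroid peak is at least mover_min_peak_distance
    # fractions away from the source peak (fall back to any other class)
    peaks = centroids.argmax(axis=1)
    resolved: dict[int, list[int]] = {}
    for k in range(config.n_classes):
        far = [j for j in range(config.n_classes)
               if j != k and abs(int(peaks[j]) - int(peaks[k])) >= config.mover_min_peak_distance]
        resolved[k] = far or [j for j in range(config.n_classes) if j != k]

    lam = config.mover_completeness
    for pid in unknown_ids:
        if pid in mixture_ids:
            a, b = rng.choice(config.n_classes, size=2, replace=False)
            centroid = 0.6 * centroids[a] + 0.4 * centroids[b]
            control_centroid[pid] = centroid
            treated_centroid[pid] = centroid
            true_ctrl[pid] = names[a]
            true_trt[pid] = names[a]
        else:
            k = int(rng.integers(config.n_classes))
            control_centroid[pid] = centroids[k]
            true_ctrl[pid] = names[k]
            if pid in mover_ids:
                new = int(resolved[k][int(rng.integers(len(resolved[k])))])
                treated_centroid[pid] = lam * centroids[new] + (1 - lam) * centroids[k]
                true_trt[pid] = names[new]
                mover_pairs[pid] = (names[k], names[new])
            else:
                treated_centroid[pid] = centroids[k]
                true_trt[pid] = names[k]

    all_ids = marker_ids + unknown_ids
    columns = [f"fraction_{f + 1}" for f in range(config.n_fractions)]

    def draw_condition(centroid_of: dict[str, np.ndarray], label: str) -> FractionationExperiment:
        tables = []
        for _ in range(config.n_replicates):
            profiles = np.vstack(
                [
                    _floor_composition(rng.dirichlet(config.concentration * centroid_of[pid]))
                    for pid in all_ids
                ]
            )
            tables.append(
                pd.DataFrame(profiles, index=pd.Index(all_ids, name="protein_id"), columns=columns)
            )
        labels = [str(r + 1) for r in range(config.n_replicates)]
        return FractionationExperiment(label, tables, labels)

    control = draw_condition(control_centroid, "control")
    treated = draw_condition(treated_centroid, "treated")
    truth = GroundTruth(
        true_class_control=true_ctrl,
        true_class_treated=true_trt,
        mover_ids=frozenset(mover_ids),
        mover_pairs=mover_pairs,
        marker_classes=marker_classes,
        mixture_ids=frozenset(mixture_ids),
    )
    return control, treated, truth


def simulate_expression_table(
    n_proteins: int,
    n_per_group: int = 5,
    n_qc: int = 5,
    effect_ids: tuple[str, ...] = (),
    log2fc: float = 0.0,
    cv_qc: float | np.ndarray = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate a whole-lysate expression table with control/treated/QC columns.

    Abundances are log-normal.  QC columns are noisy copies of the per-protein
    pool mean with multiplicative noise tuned to coefficient of variation
    ``cv_qc`` (scalar, or per-protein vector to target single proteins).
    ``effect_ids`` receive a ``log2fc`` shift in the treated group.

    Returns the table (proteins x samples, positive values) and the
    group -> column-name mapping.
    """
    rng = np.random.default_rng(seed)
    ids = [f"E{i:04d}" for i in range(n_proteins)]
    unknown_effects = set(effect_ids) - set(ids)
    if unknown_effects:
        raise ConfigError(f"effect_ids not in table: {sorted(unknown_effects)[:3]}")

    base_log2 = rng.uniform(10.0, 20.0, size=n_proteins)
    bio_sd = 0.25  # log2-scale biological + technical spread

    ctrl = 2.0 ** (base_log2[:, None] + bio_sd * rng.standard_normal((n_proteins, n_per_group)))
    shift = np.array([log2fc if pid in set(effect_ids) else 0.0 for pid in ids])
    trt = 2.0 ** (
        base_log2[:, None]
        + shift[:, None]
        + bio_sd * rng.standard_normal((n_proteins, n_per_group))
    )

    pool = np.hstack([ctrl, trt]).mean(axis=1)
    cv = np.broadcast_to(np.asarray(cv_qc, dtype=float), (n_proteins,)).copy()
    sigma = np.sqrt(np.log1p(cv**2))  # log-normal sigma giving the requested CV
    qc = pool[:, None] * np.exp(
        sigma[:, None] * rng.standard_normal((n_proteins, n_qc)) - 0.5 * sigma[:, None] ** 2
    )

    groups = {
        "control": [f"ctrl_{j + 1}" for j in range(n_per_group)],
        "treated": [f"trt_{j + 1}" for j in range(n_per_group)],
        "qc": [f"qc_{j + 1}" for j in range(n_qc)],
    }
    table = pd.DataFrame(
        np.hstack([ctrl, trt, qc]),
        index=pd.Index(ids, name="protein_id"),
        columns=groups["control"] + groups["treated"] + groups["qc"],
    )
    return table, groups
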