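"""Synthetic decoy tables with known ground truth.

Emulates the shape of a scored docking-decoy corpus — per-target decoy
ensembles, class-conditional scoring-function values of tunable
discriminative power, shared-factor feature correlation, Poisson clash
counts with occasional outliers — so every pipeline stage is testable
without the multi-gigabyte real corpus.

Each feature is a class-conditional Gaussian: for a requested ROC AUC the
class means are separated by d = sqrt(2) * Phi^{-1}(AUC) at unit total
noise variance, which makes the two-Gaussian AUC exactly the request.
Feature correlation comes from a shared per-decoy latent factor mixed
into every feature's noise at weight rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_data import CORRECT, INCORRECT, FeatureTable
from .lf_engine import HIGHER_IS_CORRECT, LOWER_IS_CORRECT

__all__ = [
    "FeatureSpec",
    "SyntheticConfig",
    "auc_to_separation",
    "separation_to_auc",
    "generate",
    "default_benchmark_features",
]


@dataclass
class FeatureSpec:
    """One synthetic scoring function: name, target AUC and orientation."""

    name: str
    auc: float
    orientation: str = HIGHER_IS_CORRECT
    noise: str = "gaussian"  # or "student_t" to stress the threshold search
    df: float = 3.0  # t degrees of freedom when noise="student_t"

    def __post_init__(self):
        if not 0.5 <= self.auc < 1.0:
            raise ValueError(f"feature AUC must lie in [0.5, 1): {self.auc}")
        if self.orientation not in (HIGHER_IS_CORRECT, LOWER_IS_CORRECT):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class SyntheticConfig:
    """Generative settings for a synthetic decoy corpus.

    ``prevalence`` is the per-target fraction of correct decoys, either a
    single float or a (lo, hi) range sampled uniformly per target to mimic
    the highly variable per-target correct fractions of real docking
    ensembles.  ``rho`` is the weight of a shared per-decoy "plausibility"
    factor that enters every feature *aligned with its orientation* — a
    generic compactness/size signal that all scoring functions mistake for
    quality.  It induces pairwise feature correlation and, because no
    combination of features can cancel it without cancelling the signal,
    bounds the jointly achievable classification accuracy the way real
    scoring-function panels plateau.  ``target_effect_sd`` adds a per-target,
    per-feature systematic offset (docking targets differ in size and
    interface chemistry, which shifts whole score distributions), so
    generalising across targets genuinely requires seeing many of them.
    Clash counts are Poisson(``clash_rate``) with a
    ``clash_outlier_frac`` fraction of decoys drawn at
    ``clash_outlier_scale`` times the rate.  Generation is fully
    determined by ``seed``.
    """

    n_targets: int = 10
    decoys_per_target: int = 500
    prevalence: float | tuple[float, float] = 0.1
    features: list[FeatureSpec] = field(default_factory=list)
    rho: float = 0.3
    target_effect_sd: float = 0.2
    clash_rate: float = 5.0
    clash_outlier_frac: float = 0.01
    clash_outlier_scale: float = 20.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = (
            (self.prevalence, self.prevalence)
            if np.isscalar(self.prevalence)
            else self.prevalence
        )
        if not (0 < lo <= hi < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not self.features:
            self.features = default_benchmark_features()


def auc_to_separation(auc: float) -> float:
    """Mean separation d of unit-variance Gaussians giving the target AUC.

    For classes N(d, 1) vs N(0, 1) the AUC is Phi(d / sqrt(2)), so
    d = sqrt(2) * Phi^{-1}(auc).
    """
    if not 0.5 <= auc < 1.0:
        raise ValueError(f"AUC must lie in [0.5, 1): {auc}")
    return float(np.sqrt(2.0) * norm.ppf(auc))


def separation_to_auc(d: float) -> float:
    """Inverse of auc_to_separation."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def default_benchmark_features(n: int | None = None) -> list[FeatureSpec]:
    """A 24-feature scoring-function panel with AUCs spread over 0.65-0.92.

    AUC levels and mixed orientations mimic a realistic public
    scoring-function panel: one strong consensus score, a spread of
    atomic and residue-contact statistical potentials (where a *low*
    potential indicates a correct pose) and interface descriptors, down
    to weak descriptors that a final LF selection should discard.
    Classifier class probabilities — the strongest LF candidates in a
    full study — are not part of the raw panel; the pipeline derives
    them by training on this panel.
    """
    H, L = HIGHER_IS_CORRECT, LOWER_IS_CORRECT
    specs = [
        ("consensus_score", 0.92, H),
        ("atom_potential_dfire", 0.88, L),
        ("atom_potential_goap", 0.85, L),
        ("buried_surface_area", 0.83, H),
        ("contact_potential_hlpl", 0.82, L),
        ("contact_potential_tsc", 0.81, L),
        ("interface_contacts", 0.80, H),
        ("atom_potential_pisa", 0.79, L),
        ("contact_potential_mj3h", 0.78, L),
        ("aliphatic_contacts", 0.78, H),
        ("contact_potential_rmfca", 0.77, L),
        ("surface_energy_model", 0.77, L),
        ("propensity_score", 0.77, H),
        ("contact_potential_tb", 0.76, L),
        ("desolvation_energy", 0.75, L),
        ("hydrophobic_patches", 0.74, H),
        ("electrostatic_energy", 0.73, L),
        ("vdw_energy", 0.72, L),
        ("polar_surface", 0.71, H),
        ("pair_potential_bt", 0.70, L),
        ("contact_potential_d1", 0.68, L),
        ("apolar_surface", 0.67, H),
        ("sipper_score", 0.66, L),
        ("pydock_energy", 0.65, L),
    ]
    if n is not None:
        specs = specs[:n]
    return [FeatureSpec(n_, a, o) for n_, a, o in specs]


def generate(config: SyntheticConfig) -> FeatureTable:
    """Generate a synthetic decoy table with gold labels.

    Each decoy draws a binary correctness label from its target's
    prevalence; each feature value is its class-conditional mean plus
    correlated noise  sqrt(rho) * z + sqrt(1 - rho) * eps  with a shared
    per-decoy factor z.  Correct decoys get a CAPRI-style quality class
    (A/M/H at realistic proportions), incorrect decoys class I.  The
    output is a standard decoy table with ``program``, ``clash_count``,
    ``capri_class`` and ``binary_label`` columns.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = (
        (config.prevalence, config.prevalence)
        if np.isscalar(config.prevalence)
        else config.prevalence
    )
    frames = []
    programs = ("ftdock", "zdock")
    for t in range(config.n_targets):
        tid = f"T{t:04d}"
        n = config.decoys_per_target
        prev = rng.uniform(lo, hi)
        y = rng.random(n) < prev
        z = rng.standard_normal(n)  # shared factor -> feature correlation
        cols = {
            "target_id": tid,
            "decoy_id": np.array([f"d{i:06d}" for i in range(n)]),
            "program": np.array([programs[i % 2] for i in range(n)]),
        }
        clashes = rng.poisson(config.clash_rate, size=n)
        outlier = rng.random(n) < config.clash_outlier_frac
        clashes[outlier] = rng.poisson(
            config.clash_rate * config.clash_outlier_scale, size=int(outlier.sum())
        )
        cols["clash_count"] = clashes
        quality = np.where(
            y,
            rng.choice(["A", "M", "H"], size=n, p=[0.85, 0.12, 0.03]),
            "I",
        )
        cols["capri_class"] = quality
        for spec in config.features:
            d = auc_to_separation(spec.auc)
            sign = 1.0 if spec.orientation == HIGHER_IS_CORRECT else -1.0
            if spec.noise == "student_t":
                eps = rng.standard_t(spec.df, size=n) / np.sqrt(
                    spec.df / (spec.df - 2)
                )
            else:
                eps = rng.standard_normal(n)
            shift = config.target_effect_sd * rng.standard_normal()
            cols[spec.name] = (
                sign * (d * y.astype(float) + np.sqrt(config.rho) * z)
                + np.sqrt(1 - config.rho) * eps
                + shift
            )
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    df["binary_label"] = np.where(df["capri_class"] == "I", INCORRECT, CORRECT)
    return FeatureTable(df)
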