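"""Synthetic intrinsic-feature populations for the subclass classifier.

Cells are drawn from per-class multivariate normal distributions over named
electrophysiological features.  A protocol-dependent shift on a subset of
features emulates the systematic offsets between recording conditions (e.g.
synaptic blockers present in Patch-seq but not in connectivity assays), and
entries are removed completely at random to emulate missing features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default feature panel mirroring the intrinsic properties measured from
#: long-square, single-spike and chirp protocols.
DEFAULT_FEATURES: tuple[str, ...] = (
    "input_resistance",
    "sag",
    "rheobase",
    "membrane_tau",
    "fi_slope",
    "adaptation_index",
    "isi_adaptation_ratio",
    "upstroke_downstroke_ratio",
    "ahp",
    "spike_width",
    "spike_threshold",
    "spike_height",
    "upstroke_adaptation_ratio",
    "impedance_peak_freq",
    "impedance_peak_ratio",
)

PROTOCOLS = ("connectivity", "patch-seq")
SUBCLASSES = ("PVALB", "non-PVALB")


@dataclass
class IntrinsicPopulationSpec:
    """Two-class Gaussian feature population with protocol structure."""

    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    class_means: dict[str, np.ndarray] | None = None
    covariance: np.ndarray | None = None
    protocol_shift: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    n_per_class: int = 100
    patch_seq_fraction: float = 0.5

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if self.class_means is None:
            # Separation concentrated on the features that dominate real
            # PVALB vs non-PVALB discrimination (fast-spiking phenotype).
            sep = np.zeros(p)
            for i, name in enumerate(self.feature_names):
                if name in (
                    "spike_height",
                    "sag",
                    "upstroke_adaptation_ratio",
                    "membrane_tau",
                    "fi_slope",
                    "spike_width",
                ):
                    sep[i] = 1.6
                else:
                    sep[i] = 0.3
            self.class_means = {"PVALB": -sep / 2.0, "non-PVALB": sep / 2.0}
        self.class_means = {k: np.asarray(v, float) for k, v in self.class_means.items()}
        if self.covariance is None:
            self.covariance = np.eye(p)
        self.covariance = np.asarray(self.covariance, float)
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape inconsistent with feature names")
        for v in self.class_means.values():
            if v.shape != (p,):
                raise ValueError("class mean length inconsistent with feature names")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        # PSD check (allow tiny negative eigenvalues from round-off)
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("covariance must be positive semi-definite")


def simulate_intrinsic_features(
    spec: IntrinsicPopulationSpec, seed: int = 0
) -> pd.DataFrame:
    """Draw a feature table with ``subclass`` and ``protocol`` columns.

    Rows are multivariate-normal draws per class; cells assigned to the
    "patch-seq" protocol get ``spec.protocol_shift`` added to the named
    features; entries are then masked to NaN completely at random at
    ``spec.missing_rate``.
    """
    rng = np.random.default_rng(seed)
    names = list(spec.feature_names)
    frames = []
    for subclass, mean in spec.class_means.items():
        n = spec.n_per_class
        if n == 0:
            continue
        X = rng.multivariate_normal(mean, spec.covariance, size=n, method="svd")
        df = pd.DataFrame(X, columns=names)
        df["subclass"] = subclass
        frames.append(df)
    if not frames:
        out = pd.DataFrame(columns=names + ["subclass", "protocol"])
        return out
    out = pd.concat(frames, ignore_index=True)
    n_total = len(out)
    protocol = np.where(
        rng.random(n_total) < spec.patch_seq_fraction, "patch-seq", "connectivity"
    )
    out["protocol"] = protocol
    for name, shift in spec.protocol_shift.items():
        out.loc[out["protocol"] == "patch-seq", name] += shift
    if spec.missing_rate > 0:
        mask = rng.random((n_total, len(names))) < spec.missing_rate
        values = out[names].to_numpy()
        values[mask] = np.nan
        out[names] = values
    return out
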