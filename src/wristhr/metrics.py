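"""Agreement metrics between estimated and ground-truth heart-rate traces.

AAE is the mean absolute error in BPM; AAEP the mean absolute relative
error in percent.  Bland-Altman agreement uses differences est - truth with
the sample (n-1) standard deviation and limits of agreement u +/- 1.96 sigma.
Classifier quality is scored by stratified k-fold cross-validation accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError
from .tracking import PeakClassifier


@dataclass
class EvalReport:
    aae: float                      # BPM
    aaep: float                     # percent
    u: float                        # mean difference, BPM
    sigma: float                    # sample std of differences, BPM
    loa: tuple                      # (u - 1.96 sigma, u + 1.96 sigma)
    pearson_r: float
    n_windows: int
    cv_accuracy: Optional[float] = None   # percent

    def to_dict(self) -> dict:
        d = {
            "aae_bpm": self.aae,
            "aaep_percent": self.aaep,
            "mean_diff_bpm": self.u,
            "sd_diff_bpm": self.sigma,
            "loa_lower_bpm": self.loa[0],
            "loa_upper_bpm": self.loa[1],
            "pearson_r": self.pearson_r,
            "n_windows": self.n_windows,
        }
        if self.cv_accuracy is not None:
            d["cv_accuracy_percent"] = self.cv_accuracy
        return d

    def summary(self) -> str:
        lines = ["Heart-rate estimation report",
                 "----------------------------"]
        for k, v in self.to_dict().items():
            lines.append(f"{k:22s} {v:.4f}" if isinstance(v, float)
                         else f"{k:22s} {v}")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _pair(est, truth):
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if est.shape != truth.shape:
        raise ParameterError(
            f"traces differ in length: {est.shape[0]} vs {truth.shape[0]}"
        )
    if est.size < 1:
        raise ParameterError("traces must be nonempty")
    return est, truth


def aae(est, truth) -> float:
    """Average absolute error (1/W) sum |est - truth| in BPM."""
    est, truth = _pair(est, truth)
    return float(np.mean(np.abs(est - truth)))


def aaep(est, truth) -> float:
    """Average absolute error percentage (1/W) sum |est - truth| / truth * 100."""
    est, truth = _pair(est, truth)
    if np.any(truth <= 0):
        raise ParameterError("truth BPM must be strictly positive for AAEP")
    return float(np.mean(np.abs(est - truth) / truth) * 100.0)


def bland_altman(est, truth):
    """Mean difference, sample std and limits of agreement of est - truth."""
    est, truth = _pair(est, truth)
    if est.size < 2:
        raise ParameterError("Bland-Altman needs at least two windows")
    d = est - truth
    u = float(np.mean(d))
    sigma = float(np.std(d, ddof=1))
    return u, sigma, (u - 1.96 * sigma, u + 1.96 * sigma)


def pearson(est, truth) -> float:
    """Sample Pearson correlation coefficient of the two traces."""
    est, truth = _pair(est, truth)
    if est.size < 2 or np.std(est) == 0 or np.std(truth) == 0:
        raise ParameterError("Pearson correlation is undefined for constant traces")
    return float(scipy.stats.pearsonr(est, truth).statistic)


def cross_validate(features, labels, k: int = 10, seed: int = 0,
                   kernel: str = "linear") -> float:
    """Mean held-out accuracy (percent) over stratified k folds, seeded."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("cross-validation needs both classes present")
    if counts.min() < k:
        raise ParameterError(
            f"smallest class has {counts.min()} members; cannot stratify "
            f"into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(features, labels):
        clf = PeakClassifier(kernel=kernel).fit(features[train_idx],
                                                labels[train_idx])
        pred = clf.predict(features[test_idx]).astype(int)
        accs.append(float(np.mean(pred == labels[test_idx])))
    return float(np.mean(accs) * 100.0)


def evaluate_trace(est, truth, cv_accuracy: Optional[float] = None) -> EvalReport:
    """Bundle all agreement metrics for one estimated trace."""
    est, truth = _pair(est, truth)
    u, sigma, loa = bland_altman(est, truth)
    return EvalReport(
        aae=aae(est, truth),
        aaep=aaep(est, truth),
        u=u, sigma=sigma, loa=loa,
        pearson_r=pearson(est, truth),
        n_windows=int(est.size),
        cv_accuracy=cv_accuracy,
    )
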