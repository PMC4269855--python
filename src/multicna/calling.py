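"""Loss/normal/gain calling of copy-number segments.

Segment means (on the log2(CN/2) ratio scale, optionally deconvolved for
tumor-cell fraction) are modelled as a three-component Gaussian mixture
with ordered means mu_loss < mu_normal < mu_gain; each segment is weighted
by its probe count.  Labels are maximum-posterior assignments, with the
full posterior retained.

Cellularity c in (0, 1] is the tumor-cell fraction of the sample: healthy
cells dilute the observed ratio r_obs = c*r_tumor + (1-c).  The correction
inverts this dilution on the ratio scale before fitting; c = 1 (pure
tumor, the default) leaves segment means untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CallModel",
    "DegenerateFitError",
    "to_log2ratio",
    "correct_cellularity",
    "fit_call_mixture",
    "assign_labels",
    "threshold_labels",
    "CallingModel",
    "CallingResults",
]

LABELS = ("loss", "normal", "gain")
_CN_FLOOR = 0.05
_RATIO_FLOOR = _CN_FLOOR / 2.0
_SD_FLOOR = 1e-3
_STATE_BAND = 0.2  # log2-ratio band around diploid reserved for 'normal'


class DegenerateFitError(ValueError):
    """Mixture fit impossible (too few segments / distinct means)."""


@dataclass(frozen=True)
class CallModel:
    """Fitted 3-state mixture over cellularity-corrected segment means."""

    means: np.ndarray      # (3,) ordered: loss < normal < gain
    sds: np.ndarray        # (3,) positive
    weights: np.ndarray    # (3,) in (0,1), summing to 1
    cellularity: float = 1.0

    def __post_init__(self):
        means = np.asarray(self.means, dtype=np.float64)
        sds = np.asarray(self.sds, dtype=np.float64)
        weights = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "weights", weights)
        if means.shape != (3,) or sds.shape != (3,) or weights.shape != (3,):
            raise ValueError("CallModel needs exactly three components")
        if not (means[0] < means[1] < means[2]):
            raise ValueError("component means must be strictly ordered loss < normal < gain")
        if (sds <= 0).any():
            raise ValueError("component sds must be positive")
        if (weights <= 0).any() or abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be positive and sum to 1")
        if not (0.0 < self.cellularity <= 1.0):
            raise ValueError("cellularity must be in (0, 1]")

    def posteriors(self, x) -> np.ndarray:
        """(n, 3) posterior responsibilities of loss/normal/gain."""
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        z = (x[:, None] - self.means[None, :]) / self.sds[None, :]
        log_pdf = -0.5 * z * z - np.log(self.sds[None, :]) + np.log(self.weights[None, :])
        log_pdf -= log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf)
        return p / p.sum(axis=1, keepdims=True)


def to_log2ratio(cn) -> np.ndarray:
    """Total copy number -> log2(CN/2); diploid maps to 0.

    Values are floored at 0.05 copies before the log so zeros are finite.
    """
    cn = np.asarray(cn, dtype=np.float64)
    return np.log2(np.maximum(cn, _CN_FLOOR) / 2.0)


def correct_cellularity(seg_log2, c: float) -> np.ndarray:
    """Deconvolve healthy-cell dilution from log2-ratio segment means.

    Observed ratio = c*tumor_ratio + (1-c), so
    corrected = log2(max((2^seg - (1-c)) / c, 0.025)).  Identity at c = 1;
    ratio 1 (log2 0, the diploid level) is a fixed point for every c.
    """
    if not (0.0 < c <= 1.0):
        raise ValueError(f"cellularity must be in (0, 1], got {c}")
    seg = np.asarray(seg_log2, dtype=np.float64)
    if c == 1.0:
        return seg.copy()
    ratio = (np.exp2(seg) - (1.0 - c)) / c
    return np.log2(np.maximum(ratio, _RATIO_FLOOR))


def fit_call_mixture(means, n_probes, *, cellularity: float = 1.0,
                     max_iter: int = 500, tol: float = 1e-10) -> CallModel:
    """Fit the 3-state ordered Gaussian mixture to segment means.

    Each segment mean (already on the log2-ratio scale) is weighted by its
    probe count.  EM starts from the weighted 0.1/0.5/0.9 quantiles (the
    normal component at the weighted median), equal mixing weights and the
    pooled sd, making the fit deterministic.  Cellularity correction is
    applied before fitting.  Component means are anchored to the diploid
    level (normal within +-0.2 log2, loss below, gain above) so that the
    labels remain diploid-relative even when a profile lacks one of the
    three states.
    """
    x = correct_cellularity(np.asarray(means, dtype=np.float64), cellularity)
    w = np.asarray(n_probes, dtype=np.float64)
    if len(x) != len(w):
        raise ValueError("means and n_probes must align")
    if len(x) < 10:
        raise DegenerateFitError(
            f"need at least 10 segments to fit the calling mixture, got {len(x)}; "
            "use the threshold fallback"
        )
    if len(np.unique(np.round(x, 12))) < 3:
        raise DegenerateFitError(
            "fewer than 3 distinct segment means: mixture fit is degenerate; "
            "use the threshold fallback"
        )
    w = w / w.sum()

    order = np.argsort(x, kind="mergesort")
    cw = np.cumsum(w[order])
    mu = np.array([x[order][np.searchsorted(cw, q)] for q in (0.1, 0.5, 0.9)])
    mu[0] = min(mu[0], -_STATE_BAND)
    mu[1] = min(max(mu[1], -_STATE_BAND), _STATE_BAND)
    mu[2] = max(mu[2], _STATE_BAND)
    # quantile init can collide when mass concentrates; nudge apart
    spread = max(x.max() - x.min(), 1e-3)
    for k in (1, 2):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + 1e-3 * spread
    pooled = max(float(np.sqrt(np.sum(w * (x - np.sum(w * x)) ** 2))), _SD_FLOOR)
    sd = np.full(3, pooled)
    pi = np.full(3, 1.0 / 3.0)

    prev = -np.inf
    for _ in range(max_iter):
        z = (x[:, None] - mu[None, :]) / sd[None, :]
        logp = -0.5 * z * z - np.log(sd[None, :]) + np.log(pi[None, :])
        m = logp.max(axis=1, keepdims=True)
        lik = np.exp(logp - m)
        tot = lik.sum(axis=1, keepdims=True)
        resp = lik / tot
        ll = float(np.sum(w * (np.log(tot[:, 0]) + m[:, 0])))

        nk = np.sum(w[:, None] * resp, axis=0)
        nk = np.maximum(nk, 1e-12)
        mu_new = np.sum(w[:, None] * resp * x[:, None], axis=0) / nk
        # homoscedastic mixture: one shared variance, matching the
        # common-variance segmentation model and avoiding the narrow/broad
        # component degeneracy of unconstrained EM
        var_shared = float(
            np.sum(w[:, None] * resp * (x[:, None] - mu_new[None, :]) ** 2)
            / nk.sum()
        )
        sd_new = np.full(3, np.sqrt(max(var_shared, _SD_FLOOR ** 2)))
        pi_new = nk / nk.sum()

        # ordering constraint: components keep their loss/normal/gain roles
        srt = np.argsort(mu_new, kind="mergesort")
        mu, sd, pi = mu_new[srt], sd_new[srt], pi_new[srt]
        # anchor the states to the diploid level: the normal component stays
        # within the +-0.2 log2 band, loss below it, gain above it; this keeps
        # the labels meaningful when a profile lacks one of the three states
        mu[0] = min(mu[0], -_STATE_BAND)
        mu[1] = min(max(mu[1], -_STATE_BAND), _STATE_BAND)
        mu[2] = max(mu[2], _STATE_BAND)
        for k in (1, 2):
            if mu[k] <= mu[k - 1]:
                mu[k] = mu[k - 1] + 1e-9
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll

    pi = np.maximum(pi, 1e-9)
    pi = pi / pi.sum()
    return CallModel(means=mu, sds=sd, weights=pi, cellularity=cellularity)


def assign_labels(segments: pd.DataFrame, model: CallModel, *,
                  mean_column: str = "mean_log2") -> pd.DataFrame:
    """Label segments by maximum posterior responsibility.

    Adds columns label, p_loss, p_normal, p_gain.  Exact posterior ties
    resolve toward 'normal'.
    """
    out = segments.copy()
    x = correct_cellularity(out[mean_column].to_numpy(), model.cellularity)
    post = CallModel(model.means, model.sds, model.weights, 1.0).posteriors(x)
    best = np.argmax(post, axis=1)
    top = post[np.arange(len(best)), best]
    tie_normal = np.isclose(post[:, 1], top, rtol=0, atol=1e-12)
    best = np.where(tie_normal, 1, best)
    out["label"] = np.array(LABELS)[best]
    out["p_loss"] = post[:, 0]
    out["p_normal"] = post[:, 1]
    out["p_gain"] = post[:, 2]
    return out


def threshold_labels(segments: pd.DataFrame, *, loss_below: float = -0.2,
                     gain_above: float = 0.2, cellularity: float = 1.0,
                     mean_column: str = "mean_log2") -> pd.DataFrame:
    """Fixed-cutoff fallback labelling for degenerate inputs."""
    out = segments.copy()
    x = correct_cellularity(out[mean_column].to_numpy(), cellularity)
    label = np.full(len(x), "normal", dtype="U6")
    label[x < loss_below] = "loss"
    label[x > gain_above] = "gain"
    out["label"] = label
    return out


class CallingModel:
    """Loss/normal/gain calling of a segment table.

    Parameters
    ----------
    segments : DataFrame
        Segment table; ``mean`` is interpreted according to ``scale``
        ('copy_number' converts via log2(CN/2), 'log2ratio' is used as-is).
    cellularity : float in (0, 1]
        Tumor-cell fraction; 1 (default) means pure tumor samples.
    pooled : bool
        Fit one mixture across all samples instead of per sample (useful
        for small cohorts with few segments per profile).
    threshold_fallback : bool
        Fall back to fixed log2-ratio cutoffs (+-0.2) when the mixture is
        degenerate for a sample.
    """

    def __init__(self, segments: pd.DataFrame, *, cellularity: float = 1.0,
                 pooled: bool = False, threshold_fallback: bool = False,
                 scale: str = "copy_number"):
        if scale not in ("copy_number", "log2ratio"):
            raise ValueError(f"unknown scale {scale!r}")
        if not (0.0 < cellularity <= 1.0):
            raise ValueError("cellularity must be in (0, 1]")
        self.segments = segments.copy()
        self.cellularity = cellularity
        self.pooled = pooled
        self.threshold_fallback = threshold_fallback
        if scale == "copy_number":
            self.segments["mean_log2"] = to_log2ratio(self.segments["mean"].to_numpy())
        else:
            self.segments["mean_log2"] = self.segments["mean"].to_numpy()

    def _fit_one(self, sub: pd.DataFrame):
        try:
            model = fit_call_mixture(
                sub["mean_log2"].to_numpy(), sub["n_probes"].to_numpy(),
                cellularity=self.cellularity,
            )
            return assign_labels(sub, model), model
        except DegenerateFitError:
            if not self.threshold_fallback:
                raise
            warnings.warn("degenerate mixture: falling back to fixed thresholds")
            return threshold_labels(sub, cellularity=self.cellularity), None

    def fit(self) -> "CallingResults":
        if self.pooled:
            labeled, model = self._fit_one(self.segments)
            models = {"<pooled>": model}
        else:
            parts, models = [], {}
            for sample, sub in self.segments.groupby("sample", sort=False):
                lab, model = self._fit_one(sub)
                parts.append(lab)
                models[sample] = model
            labeled = pd.concat(parts).sort_index()
        return CallingResults(self, labeled, models)


class CallingResults:
    """Labeled segments plus the per-sample (or pooled) mixture models."""

    def __init__(self, model: CallingModel, segments: pd.DataFrame, models: dict):
        self.model = model
        self.segments = segments
        self.mixtures = models

    def counts(self) -> pd.DataFrame:
        return (
            self.segments.groupby(["sample", "label"], sort=False)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(LABELS), fill_value=0)
        )

    def summary(self) -> str:
        lines = [
            "Copy-number calling results",
            f"  cellularity: {self.model.cellularity}",
            f"  mixtures fitted: {'pooled' if self.model.pooled else 'per sample'}",
            "",
            f"  {'sample':<16}{'loss':>7}{'normal':>8}{'gain':>7}",
        ]
        for sample, row in self.counts().iterrows():
            lines.append(
                f"  {sample:<16}{row['loss']:>7}{row['normal']:>8}{row['gain']:>7}"
            )
        return "\n".join(lines)
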