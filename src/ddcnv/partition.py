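"""Poisson partition statistics for droplet digital PCR.

A duplex ddPCR well partitions the reaction into ~15,000 droplets of ~1 nL.
Template molecules land in droplets following a Poisson law, so a droplet is
positive with probability ``1 - exp(-lambda)`` where ``lambda`` is the mean
number of template copies per droplet.  Inverting the observed fraction of
negative droplets gives the maximum-likelihood estimate

    lambda_hat = -ln(n_negative / n_total)

and the absolute concentration ``lambda_hat / droplet_volume`` in copies/µl.
The 95% confidence interval is a delta-method normal interval on the log of
``lambda_hat`` (``var(lambda_hat) = (1 - p_neg) / (n_total * p_neg)``), which
keeps the bounds strictly positive and approximately symmetric on the log
scale — the standard construction for digital PCR partition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateWellError, InvalidMergeError, SaturationError, SchemaError

__all__ = [
    "Channel",
    "TARGET_CHANNEL",
    "REFERENCE_CHANNEL",
    "DropletSpec",
    "WellCounts",
    "ConcentrationEstimate",
    "estimate_lambda",
    "lambda_variance",
    "lambda_ci",
    "concentration",
    "estimate_concentration",
    "merge_wells",
    "quantify_wells",
    "PoissonQuantifier",
]


class Channel(str, Enum):
    """Fluorescence channels of the duplex assay.

    FAM carries the target amplicon (the duplicated region, FGFR1 exon 16 in
    the original assay); HEX carries the reference amplicon (exon 8, outside
    the duplication).
    """

    TARGET_FAM = "FAM"
    REFERENCE_HEX = "HEX"


TARGET_CHANNEL = Channel.TARGET_FAM.value
REFERENCE_CHANNEL = Channel.REFERENCE_HEX.value
_VALID_CHANNELS = frozenset(c.value for c in Channel)


@dataclass(frozen=True)
class DropletSpec:
    """Physical droplet parameters of the instrument.

    Parameters
    ----------
    droplet_volume_nl : float
        Volume of one droplet in nanolitres (default 1.0).
    default_droplets_per_well : int
        Nominal accepted-droplet count of one well (default 15000).
    """

    droplet_volume_nl: float = 1.0
    default_droplets_per_well: int = 15000

    def __post_init__(self) -> None:
        if not self.droplet_volume_nl > 0:
            raise ValueError("droplet_volume_nl must be > 0")
        if self.default_droplets_per_well < 1:
            raise ValueError("default_droplets_per_well must be >= 1")

    @property
    def droplet_volume_ul(self) -> float:
        """Droplet volume in microlitres."""
        return self.droplet_volume_nl * 1e-3


@dataclass(frozen=True)
class WellCounts:
    """Accepted and positive droplet counts for one well and one channel."""

    well_id: str
    sample_id: str
    channel: str
    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.channel not in _VALID_CHANNELS:
            raise ValueError(f"channel must be one of {sorted(_VALID_CHANNELS)}, got {self.channel!r}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("n_positive must satisfy 0 <= n_positive <= n_total")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Template concentration of one channel with its 95% CI.

    ``lambda_hat`` is in copies per droplet, ``conc_copies_per_ul`` and the CI
    bounds in copies/µl.  ``saturated`` marks an all-positive well whose
    concentration is only bounded from below.
    """

    lambda_hat: float
    conc_copies_per_ul: float
    ci_low: float
    ci_high: float
    n_total: int
    n_positive: int
    saturated: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.conc_copies_per_ul <= self.ci_high):
            raise ValueError("CI bounds must bracket the point estimate")
        if self.ci_low < 0:
            raise ValueError("concentrations must be non-negative")


def _as_counts(n_total, n_positive):
    nt = np.asarray(n_total, dtype=float)
    npos = np.asarray(n_positive, dtype=float)
    if np.any(nt < 1):
        raise ValueError("n_total must be >= 1")
    if np.any((npos < 0) | (npos > nt)):
        raise ValueError("n_positive must satisfy 0 <= n_positive <= n_total")
    return nt, npos


def estimate_lambda(n_total, n_positive):
    """Maximum-likelihood mean copies per droplet, ``-ln(n_neg / n_total)``.

    Accepts scalars or arrays (broadcast).  Raises :class:`SaturationError`
    if any well is all-positive, since lambda is then unbounded above.
    """
    nt, npos = _as_counts(n_total, n_positive)
    if np.any(npos == nt):
        raise SaturationError("all droplets positive: lambda is inestimable")
    lam = -np.log((nt - npos) / nt)
    return float(lam) if lam.ndim == 0 else lam


def lambda_variance(n_total, n_positive):
    """Delta-method variance of lambda_hat: ``(1 - p_neg) / (n_total * p_neg)``."""
    nt, npos = _as_counts(n_total, n_positive)
    p_neg = (nt - npos) / nt
    if np.any(p_neg == 0):
        raise SaturationError("all droplets positive: variance undefined")
    var = (1.0 - p_neg) / (nt * p_neg)
    return float(var) if var.ndim == 0 else var


def lambda_ci(n_total, n_positive, alpha: float = 0.05):
    """Two-sided ``1 - alpha`` CI for lambda, log-normal delta method.

    Requires ``0 < n_positive < n_total`` (raise
    :class:`DegenerateWellError` otherwise): with zero or all positives only a
    one-sided bound exists — :func:`estimate_concentration` produces those.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    nt, npos = _as_counts(n_total, n_positive)
    if np.any((npos == 0) | (npos == nt)):
        raise DegenerateWellError("0 or all droplets positive: two-sided CI undefined")
    lam = -np.log((nt - npos) / nt)
    sd_log = np.sqrt(lambda_variance(nt, npos)) / lam
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    low = lam * np.exp(-z * sd_log)
    high = lam * np.exp(z * sd_log)
    if low.ndim == 0:
        return float(low), float(high)
    return low, high


def concentration(lambda_hat, spec: DropletSpec = DropletSpec()):
    """Convert copies/droplet to copies/µl: ``lambda / droplet_volume_ul``."""
    lam = np.asarray(lambda_hat, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda_hat must be >= 0")
    c = lam / spec.droplet_volume_ul
    return float(c) if c.ndim == 0 else c


def estimate_concentration(
    well: WellCounts,
    spec: DropletSpec = DropletSpec(),
    alpha: float = 0.05,
) -> ConcentrationEstimate:
    """Full per-channel estimate for one (possibly merged) well.

    Degenerate wells are not errors here: a zero-positive well reports
    concentration 0 with an exact one-sided upper bound
    (``P(no positives | lambda) = alpha``), and an all-positive well reports
    a saturated estimate with the analogous lower bound.  Both carry flags so
    the caller can decide whether merging further wells rescues them.
    """
    nt, npos = well.n_total, well.n_positive
    v = spec.droplet_volume_ul
    if npos == 0:
        lam_high = -np.log(alpha) / nt  # P(all negative) = alpha
        return ConcentrationEstimate(
            lambda_hat=0.0, conc_copies_per_ul=0.0, ci_low=0.0,
            ci_high=lam_high / v, n_total=nt, n_positive=npos,
            flags=("zero_positive",),
        )
    if npos == nt:
        lam_low = -np.log1p(-alpha ** (1.0 / nt))  # P(all positive) = alpha
        return ConcentrationEstimate(
            lambda_hat=np.inf, conc_copies_per_ul=np.inf, ci_low=lam_low / v,
            ci_high=np.inf, n_total=nt, n_positive=npos,
            saturated=True, flags=("saturated",),
        )
    lam = estimate_lambda(nt, npos)
    low, high = lambda_ci(nt, npos, alpha=alpha)
    return ConcentrationEstimate(
        lambda_hat=lam,
        conc_copies_per_ul=lam / v,
        ci_low=low / v,
        ci_high=high / v,
        n_total=nt,
        n_positive=npos,
    )


def merge_wells(wells: Sequence[WellCounts]) -> WellCounts:
    """Pool replicate wells of one sample and channel by summing counts.

    Pooling is exact for Poisson partition counts: the merged well behaves as
    a single well with the summed droplet number, which tightens the CNV
    interval roughly as 1/sqrt(k) for k equal wells.
    """
    wells = list(wells)
    if not wells:
        raise InvalidMergeError("cannot merge an empty list of wells")
    sample_ids = {w.sample_id for w in wells}
    channels = {w.channel for w in wells}
    if len(sample_ids) > 1 or len(channels) > 1:
        raise InvalidMergeError(
            f"wells span samples {sorted(sample_ids)} and channels {sorted(channels)}; "
            "merging requires a single sample and channel"
        )
    if len(wells) == 1:
        return wells[0]
    return replace(
        wells[0],
        well_id="+".join(w.well_id for w in wells),
        n_total=sum(w.n_total for w in wells),
        n_positive=sum(w.n_positive for w in wells),
    )


_WELL_COLUMNS = ["sample_id", "well_id", "channel", "n_total", "n_positive"]


def _validate_wells_frame(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise SchemaError(f"wells table is missing columns: {missing}")
    if len(wells) == 0:
        raise SchemaError("wells table is empty")
    bad = set(wells["channel"].unique()) - _VALID_CHANNELS
    if bad:
        raise SchemaError(f"unknown channel values {sorted(bad)}; expected {sorted(_VALID_CHANNELS)}")
    nt = pd.to_numeric(wells["n_total"], errors="coerce")
    npos = pd.to_numeric(wells["n_positive"], errors="coerce")
    invalid = nt.isna() | npos.isna() | (nt < 1) | (npos < 0) | (npos > nt)
    if invalid.any():
        rows = wells.index[invalid].tolist()[:5]
        raise SchemaError(f"invalid droplet counts in rows {rows}")
    out = wells.copy()
    out["n_total"] = nt.astype(int)
    out["n_positive"] = npos.astype(int)
    return out


def quantify_wells(
    wells: pd.DataFrame,
    spec: DropletSpec = DropletSpec(),
    alpha: float = 0.05,
    merge_replicates: bool = True,
) -> pd.DataFrame:
    """Per-sample×channel concentration table from a wells table.

    Input columns: ``sample_id, well_id, channel, n_total, n_positive`` with
    channel in {FAM, HEX}.  Replicate wells are pooled before estimation when
    ``merge_replicates`` (otherwise every well must be unique per
    sample×channel).  Output has one row per sample×channel with columns
    ``sample_id, channel, n_wells, n_total, n_positive, lambda,
    conc_copies_per_ul, ci_low, ci_high, flags``.
    """
    wells = _validate_wells_frame(wells)
    rows = []
    for (sample_id, channel), grp in wells.groupby(["sample_id", "channel"], sort=True):
        wlist = [
            WellCounts(str(r.well_id), str(sample_id), str(channel), int(r.n_total), int(r.n_positive))
            for r in grp.itertuples()
        ]
        if not merge_replicates and len(wlist) > 1:
            raise SchemaError(
                f"sample {sample_id} channel {channel} has {len(wlist)} wells but merging is disabled"
            )
        pooled = merge_wells(wlist)
        est = estimate_concentration(pooled, spec=spec, alpha=alpha)
        rows.append(
            {
                "sample_id": sample_id,
                "channel": channel,
                "n_wells": len(wlist),
                "n_total": pooled.n_total,
                "n_positive": pooled.n_positive,
                "lambda": est.lambda_hat,
                "conc_copies_per_ul": est.conc_copies_per_ul,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(rows)


class PoissonQuantifier(BaseEstimator, TransformerMixin):
    """Transformer mapping a droplet-count table to concentration estimates.

    A stateless sklearn-style transformer: `fit` validates the wells table
    schema, `transform` pools replicate wells and applies the Poisson
    inversion with its delta-method confidence interval.

    Parameters
    ----------
    droplet_volume_nl : float, default 1.0
        Droplet volume in nanolitres; concentrations scale with its inverse.
    alpha : float, default 0.05
        Two-sided CI significance level.
    merge_replicates : bool, default True
        Pool replicate wells per sample×channel before estimating.
    """

    def __init__(self, droplet_volume_nl: float = 1.0, alpha: float = 0.05,
                 merge_replicates: bool = True):
        self.droplet_volume_nl = droplet_volume_nl
        self.alpha = alpha
        self.merge_replicates = merge_replicates

    def _spec(self) -> DropletSpec:
        return DropletSpec(droplet_volume_nl=self.droplet_volume_nl)

    def fit(self, X: pd.DataFrame, y=None) -> "PoissonQuantifier":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        X = _validate_wells_frame(X)
        self.n_wells_ = len(X)
        self.n_samples_ = X["sample_id"].nunique()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_wells_"):
            raise AttributeError("PoissonQuantifier must be fitted before transform")
        return quantify_wells(
            X, spec=self._spec(), alpha=self.alpha, merge_replicates=self.merge_replicates
        )
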