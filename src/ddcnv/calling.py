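"""Copy-number estimation and the dual-threshold duplication call.

The copy-number value (CNV) normalizes the target/reference concentration
ratio to a diploid genome: ``CNV = 2 * c_target / c_reference``, so a normal
sample sits at 2 and a fully clonal monoallelic duplication at 3.  A sample
is called duplicated only when both the point estimate clears its cutoff
(CNV > 2.25 by default) and the lower confidence bound clears its own
(CNVmin > 2): the dual threshold keeps borderline estimates from being
called on the point value alone.  CNV = 2.25 corresponds to a target/
reference ratio of 1.125 and, under the monoallelic mixture model
(target copies per cell 2 + f, reference 2), to a duplicated-cell fraction
f = 25%.

Conclusiveness follows the assay's amplification floor: below 5 copies/µl on
either channel the ratio is too unstable to interpret and the sample is
reported inconclusive rather than forced into a call.  Low CNVmax values are
flagged (possible deletion below 2 with adequate DNA; likely artefact below
1.5) but never upgrade to a deletion call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import SaturationError, SchemaError, UndefinedRatioError
from .partition import (
    REFERENCE_CHANNEL,
    TARGET_CHANNEL,
    ConcentrationEstimate,
    DropletSpec,
    PoissonQuantifier,
    lambda_variance,
)

__all__ = [
    "Thresholds",
    "CnvEstimate",
    "CallResult",
    "TumorFractionEstimate",
    "STATUS_DUPLICATED",
    "STATUS_NON_DUPLICATED",
    "STATUS_INCONCLUSIVE",
    "ratio_for_cnv",
    "compute_cnv",
    "classify",
    "tumor_fraction",
    "call_samples",
    "DuplicationCaller",
]

STATUS_DUPLICATED = "duplicated"
STATUS_NON_DUPLICATED = "non_duplicated"
STATUS_INCONCLUSIVE = "inconclusive"

CI_METHODS = ("log_delta", "bound_ratio")


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds of the duplication assay.

    Defaults are the published operating point: duplicated requires
    CNV > 2.25 and CNVmin > 2 (strict inequalities); both channels need at
    least 5 copies/µl for a conclusive result; CNVmax below 2 flags a
    possible deletion, below 1.5 a likely technical artefact.
    """

    cnv_cutoff: float = 2.25
    cnv_min_cutoff: float = 2.0
    min_conc_copies_per_ul: float = 5.0
    deletion_flag_cnv_max: float = 2.0
    artefact_flag_cnv_max: float = 1.5

    def __post_init__(self) -> None:
        if not self.cnv_cutoff > self.cnv_min_cutoff > 0:
            raise ValueError("require cnv_cutoff > cnv_min_cutoff > 0")
        if not self.min_conc_copies_per_ul > 0:
            raise ValueError("min_conc_copies_per_ul must be > 0")


@dataclass(frozen=True)
class CnvEstimate:
    """Diploid-normalized copy number with 95% bounds."""

    cnv: float
    cnv_min: float
    cnv_max: float
    ratio: float

    def __post_init__(self) -> None:
        if not (self.cnv_min <= self.cnv <= self.cnv_max):
            raise ValueError("require cnv_min <= cnv <= cnv_max")
        if self.cnv_min <= 0:
            raise ValueError("CNV bounds must be positive")


@dataclass(frozen=True)
class TumorFractionEstimate:
    """Fraction of cells carrying one extra target copy, f = clamp(CNV - 2, 0, 1)."""

    fraction: float
    model: str = "monoallelic_duplication"


@dataclass(frozen=True)
class CallResult:
    """Duplication status with machine-readable flags and an audit trail."""

    sample_id: str
    status: str
    flags: frozenset[str] = frozenset()
    reasons: tuple[str, ...] = field(default_factory=tuple)


def ratio_for_cnv(cnv: float) -> float:
    """Target/reference concentration ratio implied by a CNV value (ratio = CNV / 2)."""
    if cnv <= 0:
        raise ValueError("cnv must be > 0")
    return cnv / 2.0


def _log_sd(est: ConcentrationEstimate) -> float:
    # sd of ln(lambda_hat) by the delta method, from the counts carried on the estimate
    var_lam = lambda_variance(est.n_total, est.n_positive)
    return math.sqrt(var_lam) / est.lambda_hat


def compute_cnv(
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    alpha: float = 0.05,
    ci_method: str = "log_delta",
) -> CnvEstimate:
    """CNV = 2 * c_target / c_reference with propagated 95% bounds.

    ``log_delta`` (default) treats the two channels as independent and adds
    their delta-method variances on the log scale:
    ``var(ln ratio) = var(ln lambda_t) + var(ln lambda_r)``, giving
    CNVmin/max = CNV * exp(∓ z * sd).  ``bound_ratio`` is the conservative
    alternative that divides opposite per-channel CI bounds.
    """
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {CI_METHODS}")
    if target.saturated or reference.saturated:
        raise SaturationError("saturated channel: CNV is inestimable")
    if reference.conc_copies_per_ul == 0:
        raise UndefinedRatioError("reference concentration is zero")
    if target.conc_copies_per_ul == 0:
        raise UndefinedRatioError("target concentration is zero; CNV bounds are degenerate")
    ratio = target.conc_copies_per_ul / reference.conc_copies_per_ul
    cnv = 2.0 * ratio
    if ci_method == "log_delta":
        sd = math.sqrt(_log_sd(target) ** 2 + _log_sd(reference) ** 2)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        cnv_min = cnv * math.exp(-z * sd)
        cnv_max = cnv * math.exp(z * sd)
    else:
        cnv_min = 2.0 * target.ci_low / reference.ci_high
        cnv_max = 2.0 * target.ci_high / reference.ci_low
    return CnvEstimate(cnv=cnv, cnv_min=cnv_min, cnv_max=cnv_max, ratio=ratio)


def tumor_fraction(cnv) -> TumorFractionEstimate:
    """Invert the monoallelic mixture model: f = clamp(CNV - 2, 0, 1).

    A tissue where a fraction f of cells carries one extra target copy has
    mean target copies per cell 2 + f against a diploid reference, hence
    CNV = 2 + f.  Accepts a :class:`CnvEstimate` or a bare CNV value.
    """
    value = cnv.cnv if isinstance(cnv, CnvEstimate) else float(cnv)
    if value <= 0:
        raise ValueError("cnv must be > 0")
    return TumorFractionEstimate(fraction=min(max(value - 2.0, 0.0), 1.0))


def classify(
    cnv: Optional[CnvEstimate],
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    thresholds: Thresholds = Thresholds(),
    sample_id: str = "",
) -> CallResult:
    """Apply the conclusiveness floor and the dual-threshold duplication rule.

    Every input maps to a status.  Priority: saturation and sub-floor
    concentrations make the sample inconclusive; otherwise duplicated needs
    CNV > cnv_cutoff AND CNVmin > cnv_min_cutoff, a split decision is
    inconclusive with a ``borderline`` flag (never non-duplicated), and the
    rest are non-duplicated.  CNVmax below the deletion level with adequate
    DNA adds ``possible_deletion``; below the artefact level adds
    ``low_cnv_artefact``.
    """
    flags: set[str] = set()
    reasons: list[str] = []
    t = thresholds

    if target.saturated or reference.saturated:
        flags.add("saturated_well")
        reasons.append("a channel is saturated (all droplets positive)")
    if target.conc_copies_per_ul < t.min_conc_copies_per_ul:
        flags.add("low_target_conc")
        reasons.append(
            f"target {target.conc_copies_per_ul:.3g} copies/ul below the "
            f"{t.min_conc_copies_per_ul:g} copies/ul conclusiveness floor"
        )
    if reference.conc_copies_per_ul < t.min_conc_copies_per_ul:
        flags.add("low_reference_conc")
        reasons.append(
            f"reference {reference.conc_copies_per_ul:.3g} copies/ul below the "
            f"{t.min_conc_copies_per_ul:g} copies/ul conclusiveness floor"
        )

    adequate = not flags

    if cnv is not None:
        if cnv.cnv_max < t.artefact_flag_cnv_max:
            flags.add("low_cnv_artefact")
            reasons.append(f"CNVmax {cnv.cnv_max:.3g} < {t.artefact_flag_cnv_max:g}: likely artefact")
        if adequate and cnv.cnv_max < t.deletion_flag_cnv_max:
            flags.add("possible_deletion")
            reasons.append(f"CNVmax {cnv.cnv_max:.3g} < {t.deletion_flag_cnv_max:g}: possible deletion")

    if not adequate:
        return CallResult(sample_id, STATUS_INCONCLUSIVE, frozenset(flags), tuple(reasons))
    if cnv is None:
        reasons.append("CNV could not be computed")
        return CallResult(sample_id, STATUS_INCONCLUSIVE, frozenset(flags), tuple(reasons))

    above_cnv = cnv.cnv > t.cnv_cutoff
    above_min = cnv.cnv_min > t.cnv_min_cutoff
    if above_cnv and above_min:
        reasons.append(
            f"CNV {cnv.cnv:.3g} > {t.cnv_cutoff:g} and CNVmin {cnv.cnv_min:.3g} > {t.cnv_min_cutoff:g}"
        )
        return CallResult(sample_id, STATUS_DUPLICATED, frozenset(flags), tuple(reasons))
    if above_cnv != above_min:
        flags.add("borderline")
        reasons.append(
            f"cutoffs disagree (CNV {cnv.cnv:.3g} vs {t.cnv_cutoff:g}, "
            f"CNVmin {cnv.cnv_min:.3g} vs {t.cnv_min_cutoff:g}): re-test advised"
        )
        return CallResult(sample_id, STATUS_INCONCLUSIVE, frozenset(flags), tuple(reasons))
    reasons.append(f"CNV {cnv.cnv:.3g} <= {t.cnv_cutoff:g}")
    return CallResult(sample_id, STATUS_NON_DUPLICATED, frozenset(flags), tuple(reasons))


def _estimate_from_row(row: dict) -> ConcentrationEstimate:
    raw_flags = row.get("flags", "")
    flags = tuple(f for f in str(raw_flags).split(";") if f) if isinstance(raw_flags, str) else ()
    return ConcentrationEstimate(
        lambda_hat=float(row["lambda"]),
        conc_copies_per_ul=float(row["conc_copies_per_ul"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        n_total=int(row["n_total"]),
        n_positive=int(row["n_positive"]),
        saturated="saturated" in flags,
        flags=flags,
    )


def call_samples(
    concentrations: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    alpha: float = 0.05,
    ci_method: str = "log_delta",
) -> pd.DataFrame:
    """Per-sample duplication calls from a concentration table.

    Expects the :func:`ddcnv.partition.quantify_wells` output (one row per
    sample×channel, channels FAM and HEX).  Returns one row per sample:
    ``sample_id, cnv, cnv_min, cnv_max, ratio, tumor_fraction, status, flags``.
    """
    required = {"sample_id", "channel", "n_total", "n_positive", "lambda",
                "conc_copies_per_ul", "ci_low", "ci_high"}
    missing = required - set(concentrations.columns)
    if missing:
        raise SchemaError(f"concentration table is missing columns: {sorted(missing)}")
    if "flags" not in concentrations.columns:
        concentrations = concentrations.assign(flags="")
    rows = []
    for sample_id, grp in concentrations.groupby("sample_id", sort=True):
        by_channel = {r["channel"]: r for r in grp.to_dict("records")}
        for ch in (TARGET_CHANNEL, REFERENCE_CHANNEL):
            if ch not in by_channel:
                raise SchemaError(f"sample {sample_id} is missing channel {ch}")
        target = _estimate_from_row(by_channel[TARGET_CHANNEL])
        reference = _estimate_from_row(by_channel[REFERENCE_CHANNEL])
        try:
            cnv = compute_cnv(target, reference, alpha=alpha, ci_method=ci_method)
        except (SaturationError, UndefinedRatioError):
            cnv = None
        result = classify(cnv, target, reference, thresholds, sample_id=str(sample_id))
        frac = tumor_fraction(cnv).fraction if cnv is not None else np.nan
        rows.append(
            {
                "sample_id": sample_id,
                "cnv": cnv.cnv if cnv else np.nan,
                "cnv_min": cnv.cnv_min if cnv else np.nan,
                "cnv_max": cnv.cnv_max if cnv else np.nan,
                "ratio": cnv.ratio if cnv else np.nan,
                "tumor_fraction": frac,
                "status": result.status,
                "flags": ";".join(sorted(result.flags)),
            }
        )
    return pd.DataFrame(rows)


class DuplicationCaller(BaseEstimator):
    """Rule-based duplication classifier over droplet-count tables.

    sklearn-style estimator: `fit` validates the wells table and freezes the
    threshold set; `predict` returns the duplication status per sample;
    `call_table` returns the full per-sample CNV/call table.  There is no
    training step — the thresholds are the published operating point — but
    the estimator surface makes the caller composable with sklearn tooling
    (get_params/set_params, clone, pipelines).

    Parameters mirror :class:`Thresholds` plus the quantification settings
    (droplet volume, CI level and method, replicate merging).
    """

    def __init__(
        self,
        cnv_cutoff: float = 2.25,
        cnv_min_cutoff: float = 2.0,
        min_conc_copies_per_ul: float = 5.0,
        deletion_flag_cnv_max: float = 2.0,
        artefact_flag_cnv_max: float = 1.5,
        alpha: float = 0.05,
        droplet_volume_nl: float = 1.0,
        ci_method: str = "log_delta",
        merge_replicates: bool = True,
    ):
        self.cnv_cutoff = cnv_cutoff
        self.cnv_min_cutoff = cnv_min_cutoff
        self.min_conc_copies_per_ul = min_conc_copies_per_ul
        self.deletion_flag_cnv_max = deletion_flag_cnv_max
        self.artefact_flag_cnv_max = artefact_flag_cnv_max
        self.alpha = alpha
        self.droplet_volume_nl = droplet_volume_nl
        self.ci_method = ci_method
        self.merge_replicates = merge_replicates

    def fit(self, X: pd.DataFrame, y=None) -> "DuplicationCaller":
        if self.ci_method not in CI_METHODS:
            raise ValueError(f"ci_method must be one of {CI_METHODS}")
        self.thresholds_ = Thresholds(
            cnv_cutoff=self.cnv_cutoff,
            cnv_min_cutoff=self.cnv_min_cutoff,
            min_conc_copies_per_ul=self.min_conc_copies_per_ul,
            deletion_flag_cnv_max=self.deletion_flag_cnv_max,
            artefact_flag_cnv_max=self.artefact_flag_cnv_max,
        )
        self.quantifier_ = PoissonQuantifier(
            droplet_volume_nl=self.droplet_volume_nl,
            alpha=self.alpha,
            merge_replicates=self.merge_replicates,
        ).fit(X)
        self.classes_ = np.array(
            [STATUS_DUPLICATED, STATUS_INCONCLUSIVE, STATUS_NON_DUPLICATED]
        )
        return self

    def call_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-sample call table for a wells table."""
        if not hasattr(self, "thresholds_"):
            raise AttributeError("DuplicationCaller must be fitted before calling")
        conc = self.quantifier_.transform(X)
        return call_samples(
            conc, thresholds=self.thresholds_, alpha=self.alpha, ci_method=self.ci_method
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Duplication status per sample, in sorted sample_id order."""
        return self.call_table(X)["status"].to_numpy()
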