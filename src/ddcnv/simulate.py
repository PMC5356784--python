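"""Seeded synthetic droplet-count data with known ground truth.

The study's per-well droplet counts are not publicly deposited, so this
module emulates them: droplets receive template by ideal Poisson
partitioning, hence the positive count of a well is
``Binomial(n_droplets, 1 - exp(-c * V))`` for concentration ``c`` (copies/µl)
and droplet volume ``V`` (µl).  A sample is a pair of channels generated
from the monoallelic mixture model — a fraction ``f`` of cells carries one
extra target copy, so the target channel runs at ``reference * (2 + f) / 2``
— with optional FFPE-style knobs: a shared ``degradation`` factor scaling
both channels (amplifiable-fraction loss, which moves samples across the
conclusiveness floor but leaves the CNV ratio unbiased) and a target-only
``channel_imbalance`` factor that injects the low-CNV artefact seen in
degraded material.

Accepted droplet counts per well are drawn log-uniformly over the observed
instrument range 7,177–47,840 unless fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .calling import STATUS_DUPLICATED, STATUS_INCONCLUSIVE, STATUS_NON_DUPLICATED, Thresholds
from .partition import REFERENCE_CHANNEL, TARGET_CHANNEL, WellCounts

__all__ = [
    "DROPLET_RANGE",
    "DEFAULT_COHORT_COMPOSITION",
    "DEFAULT_DUPLICATION_PREVALENCE",
    "SimSampleConfig",
    "simulate_well",
    "simulate_sample",
    "simulate_cohort",
]

# accepted-droplet range observed on the instrument (min, max); median ~15,691
DROPLET_RANGE = (7177, 47840)

DEFAULT_COHORT_COMPOSITION: Mapping[str, int] = {
    "DNT": 12, "PTO": 2, "PDA": 3, "GG": 14, "PA": 5,
}
DEFAULT_DUPLICATION_PREVALENCE: Mapping[str, float] = {
    "DNT": 5 / 12, "PTO": 0.0, "PDA": 0.0, "GG": 0.0, "PA": 0.0,
}


@dataclass
class SimSampleConfig:
    """Ground-truth description of one simulated sample.

    ``true_fraction`` is the duplicated-cell fraction f; ``reference_conc``
    the pre-degradation reference concentration in copies/µl;
    ``droplets_per_well`` either a fixed count or an inclusive (low, high)
    range sampled log-uniformly per well.
    """

    sample_id: str
    true_fraction: float = 0.0
    reference_conc: float = 50.0
    n_wells: int = 1
    droplets_per_well: Union[int, tuple[int, int]] = DROPLET_RANGE
    droplet_volume_nl: float = 1.0
    degradation: float = 1.0
    channel_imbalance: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must be in [0, 1]")
        if self.reference_conc < 0:
            raise ValueError("reference_conc must be >= 0")
        if not 0.0 < self.degradation <= 1.0:
            raise ValueError("degradation must be in (0, 1]")
        if self.channel_imbalance < 0:
            raise ValueError("channel_imbalance must be >= 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")

    @property
    def target_conc(self) -> float:
        """Effective target-channel concentration in copies/µl."""
        return (
            self.reference_conc * (2.0 + self.true_fraction) / 2.0
            * self.degradation * self.channel_imbalance
        )

    @property
    def effective_reference_conc(self) -> float:
        return self.reference_conc * self.degradation


def _draw_droplets(droplets_per_well, rng: np.random.Generator) -> int:
    if isinstance(droplets_per_well, (int, np.integer)):
        return int(droplets_per_well)
    low, high = droplets_per_well
    return int(round(np.exp(rng.uniform(np.log(low), np.log(high)))))


def simulate_well(
    conc: float,
    n_droplets: int,
    volume_nl: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    *,
    sample_id: str = "S1",
    well_id: str = "W1",
    channel: str = TARGET_CHANNEL,
) -> WellCounts:
    """Draw one well: positives ~ Binomial(n_droplets, 1 - exp(-conc * V_ul))."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(rng)
    p_pos = -np.expm1(-conc * volume_nl * 1e-3)
    n_positive = int(rng.binomial(n_droplets, p_pos))
    return WellCounts(well_id, sample_id, channel, int(n_droplets), n_positive)


def simulate_sample(
    cfg: SimSampleConfig, rng: Optional[np.random.Generator] = None
) -> list[WellCounts]:
    """Simulate all wells of one sample, both channels.

    Both channels of a well share the same accepted-droplet count, as on the
    instrument (one emulsion read in two colors).  With
    ``channel_imbalance = 1`` the expected CNV of the downstream pipeline is
    ``2 + true_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    wells: list[WellCounts] = []
    for i in range(cfg.n_wells):
        n = _draw_droplets(cfg.droplets_per_well, rng)
        for channel, conc in (
            (TARGET_CHANNEL, cfg.target_conc),
            (REFERENCE_CHANNEL, cfg.effective_reference_conc),
        ):
            wells.append(
                simulate_well(
                    conc, n, cfg.droplet_volume_nl, rng,
                    sample_id=cfg.sample_id, well_id=f"{cfg.sample_id}_w{i + 1}",
                    channel=channel,
                )
            )
    return wells


def _expected_call(cfg: SimSampleConfig, thresholds: Thresholds) -> str:
    if (
        cfg.target_conc < thresholds.min_conc_copies_per_ul
        or cfg.effective_reference_conc < thresholds.min_conc_copies_per_ul
    ):
        return STATUS_INCONCLUSIVE
    true_cnv = (2.0 + cfg.true_fraction) * cfg.channel_imbalance
    if true_cnv > thresholds.cnv_cutoff:
        return STATUS_DUPLICATED
    return STATUS_NON_DUPLICATED


def simulate_cohort(
    n_per_group: Optional[Mapping[str, int]] = None,
    duplication_prevalence: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    *,
    reference_conc_range: tuple[float, float] = (2.0, 200.0),
    duplicated_fraction_range: tuple[float, float] = (0.75, 1.0),
    n_wells: int = 1,
    droplets_per_well: Union[int, tuple[int, int]] = DROPLET_RANGE,
    droplet_volume_nl: float = 1.0,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (wells table, truth table).

    Group sizes default to the study composition (12 DNT, 2 PTO, 3 PDA,
    14 GG, 5 PA) with duplication confined to DNT at prevalence 5/12.  The
    duplicated count per group is deterministic
    (``round(prevalence * n)``; which samples carry it is randomized), so
    the default cohort contains exactly 5 duplicated DNT samples.
    Duplicated samples draw f uniformly from ``duplicated_fraction_range``
    (default 0.75–1, matching the observed duplicated CNV band 2.75–3);
    non-duplicated samples have f = 0.  Reference
    concentrations are log-uniform over ``reference_conc_range``, which
    spans sub-threshold FFPE extractions through well-amplifying ones.

    The truth table columns are ``sample_id, diagnosis, true_fraction,
    reference_conc, degradation, expected_call``.
    """
    rng = np.random.default_rng(seed)
    n_per_group = dict(DEFAULT_COHORT_COMPOSITION if n_per_group is None else n_per_group)
    prevalence = dict(
        DEFAULT_DUPLICATION_PREVALENCE if duplication_prevalence is None else duplication_prevalence
    )
    well_rows: list[WellCounts] = []
    truth_rows: list[dict] = []
    for diagnosis, n in n_per_group.items():
        if n < 0:
            raise ValueError("group sizes must be >= 0")
        n_dup = int(round(prevalence.get(diagnosis, 0.0) * n))
        dup_mask = np.zeros(n, dtype=bool)
        dup_mask[:n_dup] = True
        rng.shuffle(dup_mask)
        for i in range(n):
            f = float(rng.uniform(*duplicated_fraction_range)) if dup_mask[i] else 0.0
            ref_conc = float(
                np.exp(rng.uniform(np.log(reference_conc_range[0]), np.log(reference_conc_range[1])))
            )
            cfg = SimSampleConfig(
                sample_id=f"{diagnosis}{i + 1:02d}",
                true_fraction=f,
                reference_conc=ref_conc,
                n_wells=n_wells,
                droplets_per_well=droplets_per_well,
                droplet_volume_nl=droplet_volume_nl,
            )
            well_rows.extend(simulate_sample(cfg, rng))
            truth_rows.append(
                {
                    "sample_id": cfg.sample_id,
                    "diagnosis": diagnosis,
                    "true_fraction": f,
                    "reference_conc": ref_conc,
                    "degradation": cfg.degradation,
                    "expected_call": _expected_call(cfg, thresholds),
                }
            )
    wells = pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in well_rows],
            "well_id": [w.well_id for w in well_rows],
            "channel": [w.channel for w in well_rows],
            "n_total": [w.n_total for w in well_rows],
            "n_positive": [w.n_positive for w in well_rows],
        }
    )
    return wells, pd.DataFrame(truth_rows)
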