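"""Scalar AA-CSIA trophic statistics.

Trophic position from the glutamic acid - phenylalanine d15N spacing::

    TP = (d15N_Glx - d15N_Phe - beta) / Delta + 1

with ``beta`` the producer Glx-Phe offset (3.4 permil) and ``Delta`` the
per-trophic-step enrichment (7.6 permil).  Uncertainty is first-order
error propagation over the two measured deltas and, optionally, the
beta/Delta parameters::

    sd(TP) = sqrt(s_Glx^2 + s_Phe^2 + s_beta^2 + ((TP-1) s_Delta)^2) / Delta

The percent-heterotrophy estimate is a linear two-end-member mixing
model on trophic position,

    f = (TP_mix - TP_auto) / (TP_het - TP_auto),

with the Phillips-Gregg first-order variance

    var(f) = [s_mix^2 + f^2 s_het^2 + (1-f)^2 s_auto^2] / (TP_het - TP_auto)^2.

Also provided: the inverse-variance weighted mean of d15N values (a
trophic proxy that avoids assumed beta/Delta constants) and the sum-V
index of heterotrophic amino-acid resynthesis, the mean absolute
deviation of trophic-AA d15N values within a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AAIsotopeTable
from .registry import SUMV_TROPHIC_SET

__all__ = [
    "TpParameters",
    "TrophicPosition",
    "HeterotrophyEstimate",
    "SumVResult",
    "trophic_position",
    "weighted_mean_d15n",
    "sum_v",
    "heterotrophy_fraction",
    "scenario_table",
    "tp_table",
]

#: Named heterotrophic end-member scenarios: feeding on primary producers
#: / algal detritus (prey TP 1 -> consumer TP 2) and on zooplankton
#: (prey TP 2 -> consumer TP 3).
DEFAULT_SCENARIOS: dict[str, tuple[float, float]] = {
    "detritivory": (2.0, 0.0),
    "zooplanktivory": (3.0, 0.0),
}


@dataclass(frozen=True)
class TpParameters:
    """Constants of the Glx-Phe trophic position equation (permil)."""

    beta: float = 3.4
    delta_tef: float = 7.6
    sd_beta: float = 0.0
    sd_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_tef <= 0:
            raise ValueError("trophic enrichment factor Delta must be > 0")
        if self.sd_beta < 0 or self.sd_delta < 0:
            raise ValueError("parameter sd terms must be >= 0")


@dataclass(frozen=True)
class TrophicPosition:
    """Trophic position estimate with its propagated standard deviation."""

    tp: float
    sd: float
    d15n_glx: float
    d15n_phe: float
    sd_glx: float
    sd_phe: float
    params: TpParameters = field(default=TpParameters())

    def __post_init__(self) -> None:
        if not math.isfinite(self.tp):
            raise ValueError("trophic position is not finite")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class HeterotrophyEstimate:
    """Mixing fraction of heterotrophy with propagated sd.

    ``fraction`` is unbounded in principle: values outside [0, 1] are
    reported as-is with ``in_range=False`` (a flag for data/end-member
    inconsistency) rather than clamped.
    """

    fraction: float
    sd: float
    scenario: str
    tp_auto: tuple[float, float]
    tp_het: tuple[float, float]

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_sd(self) -> float:
        return 100.0 * self.sd

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.fraction <= 1.0


@dataclass(frozen=True)
class SumVResult:
    """Sum-V index with the per-AA deviations that produced it."""

    sum_v: float
    aa_used: tuple[str, ...]
    deviations: tuple[float, ...]


def trophic_position(
    d15n_glx: float,
    d15n_phe: float,
    sd_glx: float = 0.0,
    sd_phe: float = 0.0,
    params: TpParameters = TpParameters(),
) -> TrophicPosition:
    """Glx-Phe trophic position with first-order error propagation.

    By default only the analytical replicate uncertainties of the two
    amino acids enter the propagated sd; set ``params.sd_beta`` /
    ``params.sd_delta`` for full parameter-uncertainty propagation.
    """
    for name, v in (("d15n_glx", d15n_glx), ("d15n_phe", d15n_phe)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if sd_glx < 0 or sd_phe < 0:
        raise ValueError("analytical sd terms must be >= 0")
    tp = (d15n_glx - d15n_phe - params.beta) / params.delta_tef + 1.0
    var = (
        sd_glx**2
        + sd_phe**2
        + params.sd_beta**2
        + ((tp - 1.0) * params.sd_delta) ** 2
    )
    sd = math.sqrt(var) / params.delta_tef
    return TrophicPosition(tp, sd, d15n_glx, d15n_phe, sd_glx, sd_phe, params)


def weighted_mean_d15n(
    values: Sequence[float],
    sds: Sequence[float],
    zero_sd_override: bool = False,
) -> float:
    """Inverse-variance weighted mean of d15N values.

    A replicate sd of exactly zero means an infinite weight and almost
    always indicates degenerate input; it is an error unless
    ``zero_sd_override`` substitutes the smallest positive sd present.
    """
    x = np.asarray(values, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.size == 0:
        raise ValueError("weighted mean of empty input")
    if x.shape != s.shape:
        raise ValueError("values and sds must have equal length")
    if (s < 0).any():
        raise ValueError("sds must be >= 0")
    if (s == 0).any():
        if not zero_sd_override:
            raise ValueError(
                "sd of 0 gives infinite weight; pass zero_sd_override=True "
                "to substitute the smallest positive sd"
            )
        pos = s[s > 0]
        if pos.size == 0:
            raise ValueError("all sds are zero; weighted mean undefined")
        s = np.where(s == 0, pos.min(), s)
    w = 1.0 / s**2
    return float(np.sum(w * x) / np.sum(w))


def sum_v(
    table: AAIsotopeTable,
    sample_id: str,
    aa_set: Sequence[str] = tuple(SUMV_TROPHIC_SET),
) -> SumVResult:
    """Sum-V microbial-resynthesis index for one sample.

    Mean absolute deviation of the trophic-AA d15N values about their
    mean: ``sum_v = (1/n) * sum(|x_i - mean(x)|)``.
    """
    codes = [table.registry.normalize(a) for a in aa_set]
    values, missing = [], []
    for code in codes:
        try:
            delta, _ = table.value(sample_id, code, "N")
            values.append(delta)
        except KeyError:
            missing.append(code)
    if missing:
        raise ValueError(
            f"sample {sample_id!r} lacks d15N for amino acid(s): {missing}"
        )
    return sum_v_values(values, codes)


def sum_v_values(values: Sequence[float], codes: Sequence[str]) -> SumVResult:
    """Sum-V from raw d15N values (codes recorded for provenance)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("sum_v of empty input")
    chi = x - x.mean()
    return SumVResult(
        sum_v=float(np.mean(np.abs(chi))),
        aa_used=tuple(codes),
        deviations=tuple(float(c) for c in chi),
    )


def heterotrophy_fraction(
    tp_mix: TrophicPosition | tuple[float, float],
    tp_auto: tuple[float, float] = (1.0, 0.0),
    tp_het: tuple[float, float] = (2.0, 0.0),
    scenario: str = "custom",
) -> HeterotrophyEstimate:
    """Two-end-member mixing fraction of heterotrophy on the TP scale.

    ``tp_mix`` may be a :class:`TrophicPosition` or a ``(tp, sd)`` pair;
    the end-members are ``(tp, sd)`` pairs.  The variance is the
    Phillips-Gregg first-order Taylor form.
    """
    if isinstance(tp_mix, TrophicPosition):
        mix, s_mix = tp_mix.tp, tp_mix.sd
    else:
        mix, s_mix = tp_mix
    a, s_a = tp_auto
    h, s_h = tp_het
    span = h - a
    if span == 0:
        raise ValueError("degenerate end-members: tp_het equals tp_auto")
    f = (mix - a) / span
    var = (s_mix**2 + f**2 * s_h**2 + (1.0 - f) ** 2 * s_a**2) / span**2
    return HeterotrophyEstimate(
        fraction=float(f),
        sd=float(math.sqrt(var)),
        scenario=scenario,
        tp_auto=(a, s_a),
        tp_het=(h, s_h),
    )


def tp_table(
    table: AAIsotopeTable,
    params: TpParameters = TpParameters(),
    fractions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample trophic positions for every sample with Glx and Phe d15N."""
    rows = []
    for rec in table.samples.itertuples(index=False):
        if fractions is not None and rec.fraction not in fractions:
            continue
        try:
            glx, s_glx = table.value(rec.sample_id, "Glx", "N")
            phe, s_phe = table.value(rec.sample_id, "Phe", "N")
        except KeyError:
            continue
        est = trophic_position(glx, phe, s_glx, s_phe, params)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "fraction": rec.fraction,
                "treatment": rec.treatment,
                "tp": est.tp,
                "tp_sd": est.sd,
            }
        )
    if not rows:
        raise ValueError("no sample has both Glx and Phe d15N values")
    return pd.DataFrame(rows)


def scenario_table(
    tps: pd.DataFrame,
    scenarios: Mapping[str, tuple[float, float]] | None = None,
    tp_auto: tuple[float, float] = (1.0, 0.0),
    group_by: Sequence[str] = ("fraction", "treatment"),
) -> dict[str, pd.DataFrame]:
    """Full samples x scenarios grid of heterotrophy estimates.

    Parameters
    ----------
    tps
        Per-sample TP frame as returned by :func:`tp_table` (columns
        ``sample_id, tp, tp_sd`` plus grouping metadata).
    scenarios
        Mapping scenario name -> heterotrophic end-member ``(tp, sd)``;
        defaults to detritivory (TP 2.0) and zooplanktivory (TP 3.0).

    Returns
    -------
    dict with ``"estimates"`` (one row per sample x scenario, percent
    scale) and ``"summary"`` (group mean +/- SD over samples).
    """
    if scenarios is None:
        scenarios = DEFAULT_SCENARIOS
    if len(tps) == 0:
        raise ValueError("empty sample list")
    rows = []
    for rec in tps.itertuples(index=False):
        for name, het in scenarios.items():
            est = heterotrophy_fraction((rec.tp, rec.tp_sd), tp_auto, het, scenario=name)
            row = {c: getattr(rec, c, None) for c in tps.columns}
            row.update(
                scenario=name,
                fraction_het=est.fraction,
                fraction_sd=est.sd,
                percent_het=est.percent,
                percent_sd=est.percent_sd,
                in_range=est.in_range,
            )
            rows.append(row)
    estimates = pd.DataFrame(rows)
    keys = ["scenario"] + [c for c in group_by if c in estimates.columns]
    summary = (
        estimates.groupby(keys, dropna=False)["percent_het"]
        .agg(mean_percent="mean", sd_percent="std", n="count")
        .reset_index()
    )
    return {"estimates": estimates, "summary": summary}
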