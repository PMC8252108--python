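"""Synthetic AA-isotope datasets with the structure the analysis assumes.

The generator emulates the statistical shape of a coral-Symbiodiniaceae
feeding experiment: host and symbiont tissue fractions sampled across
three nutrition treatments (Light-Not-Fed, Light-Fed, Dark-Fed) and two
genets, plus a plankton end-member.  Per group it fixes latent per-AA
mean d13C and d15N profiles; the Glx-Phe d15N spacing is set from a
target trophic position as ``beta + (TP - 1) * Delta`` so that hosts and
symbionts look like primary producers (TP 1) and plankton like a
consumer (TP 2).  Replicate injections are independent Gaussian draws
around the latent mean with a configurable analytical sd; an optional
per-sample baseline shift (common to all amino acids of a sample)
emulates the baseline isotope variation that mean-normalization is
designed to remove.

The exact latent values used for a dataset are always returned (and can
be serialized) as :class:`GroundTruth`, so parameter-recovery tests
never have to re-derive them.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data import AAIsotopeTable
from .registry import MEASURED_13

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "paper_preset",
    "generate_dataset",
    "inject_trophic_shift",
]

#: Baseline (host) per-AA mean d13C profile, permil vs V-PDB.  Values
#: span the range typical of shallow-water coral host tissue (about -24
#: to -8 permil), with glycine the most 13C-enriched amino acid.
HOST_D13C: dict[str, float] = {
    "Ala": -15.0, "Asp": -14.5, "Glx": -13.5, "Gly": -8.5, "Ile": -18.0,
    "Leu": -21.5, "Lys": -16.5, "Phe": -19.5, "Pro": -16.0, "Ser": -11.5,
    "Thr": -12.5, "Tyr": -20.5, "Val": -17.5,
}

#: Baseline (host) per-AA mean d15N profile, permil vs Air.  Trophic
#: amino acids sit higher than source amino acids; Glx is overwritten
#: from the group's target trophic position.
HOST_D15N: dict[str, float] = {
    "Ala": 4.5, "Asp": 4.0, "Glx": 4.4, "Gly": 1.5, "Ile": 4.2,
    "Leu": 4.8, "Lys": 0.5, "Phe": 1.0, "Pro": 4.6, "Ser": 1.8,
    "Thr": 0.0, "Tyr": 2.0, "Val": 4.4,
}

#: Symbiont d13C offset pattern relative to host (mean about -0.9
#: permil): essential AAs nearly identical to the host, with the
#: largest depletions in the nonessential Gly and Glx.
SYMBIONT_C_DEV: dict[str, float] = {
    "Ala": -2.0, "Asp": -0.5, "Glx": -2.5, "Gly": -3.0, "Ile": -0.2,
    "Leu": -0.3, "Lys": -0.1, "Phe": -0.4, "Pro": -1.5, "Ser": -0.2,
    "Thr": -0.3, "Tyr": -0.1, "Val": -0.3,
}

#: Plankton d13C offset pattern relative to host (mean exactly -5.5
#: permil).  The offsets are amino-acid specific — strongest in Ile,
#: Lys and Thr — so the *pattern* survives mean-normalization and the
#: plankton fingerprint stays separable from coral tissues.
PLANKTON_C_DEV: dict[str, float] = {
    "Ala": -4.0, "Asp": -5.0, "Glx": -4.5, "Gly": -2.5, "Ile": -8.5,
    "Leu": -5.0, "Lys": -8.0, "Phe": -4.5, "Pro": -5.0, "Ser": -3.0,
    "Thr": -8.5, "Tyr": -5.5, "Val": -7.5,
}

#: Symbiont d15N offset pattern relative to host: Leu/Pro/Asp slightly
#: depleted, Gly/Thr/Tyr enriched in the symbiont; Glx and Phe are
#: untouched so host and symbiont share the producer trophic position.
SYMBIONT_N_DEV: dict[str, float] = {
    "Ala": 0.0, "Asp": -0.5, "Glx": 0.0, "Gly": 1.0, "Ile": 0.0,
    "Leu": -0.8, "Lys": 0.0, "Phe": 0.0, "Pro": -0.9, "Ser": 0.0,
    "Thr": 0.8, "Tyr": 1.5, "Val": 0.0,
}


@dataclass
class SyntheticConfig:
    """Full latent specification of a synthetic dataset.

    ``means`` holds, per (group, element), the per-AA latent mean; the
    Glx d15N mean of each group is derived from ``tp_targets`` via the
    group's Phe mean and the beta/Delta constants at construction time
    (see :func:`paper_preset`), so editing ``means`` directly is the way
    to inject arbitrary effects.
    """

    aa_codes: list[str] = field(default_factory=lambda: list(MEASURED_13))
    means: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    tp_targets: dict[str, float] = field(default_factory=dict)
    beta: float = 3.4
    delta_tef: float = 7.6
    treatments: list[str] = field(default_factory=lambda: ["L-NF", "L-F", "D-F"])
    treatment_effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    analytical_sd: dict[str, float] = field(default_factory=lambda: {"C": 0.3, "N": 0.3})
    baseline_shift_sd: dict[str, float] = field(default_factory=lambda: {"C": 0.0, "N": 0.0})
    n_rep: int = 3
    n_genets: int = 2
    n_plankton: int = 1
    study: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.means:
            raise ValueError("config has no group mean profiles")
        if any(sd <= 0 for sd in self.analytical_sd.values()):
            raise ValueError("analytical sd must be > 0 for every element")
        if any(sd < 0 for sd in self.baseline_shift_sd.values()):
            raise ValueError("baseline shift sd must be >= 0")
        if any(tp < 0 for tp in self.tp_targets.values()):
            raise ValueError("TP targets must be >= 0")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2 to estimate a replicate sd")
        for (group, element), profile in self.means.items():
            missing = [a for a in self.aa_codes if a not in profile]
            if missing:
                raise ValueError(f"group {group!r} element {element!r} lacks means for {missing}")

    @property
    def groups(self) -> list[str]:
        return sorted({g for g, _ in self.means})

    def copy(self) -> "SyntheticConfig":
        return copy.deepcopy(self)


@dataclass
class GroundTruth:
    """Exact latent quantities behind one generated dataset."""

    means: dict[str, dict[str, float]]  # "group/element" -> {aa: mean}
    tp_targets: dict[str, float]
    treatment_effects: dict[str, dict[str, float]]
    analytical_sd: dict[str, float]
    seed: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _glx_from_tp(phe: float, tp: float, beta: float, delta: float) -> float:
    return phe + beta + (tp - 1.0) * delta


def paper_preset(
    n_genets: int = 2,
    n_plankton: int = 1,
    analytical_sd: float = 0.3,
    baseline_shift_sd: Mapping[str, float] | None = None,
    plankton_c_offset: float = -5.5,
    plankton_n_offset: float = 2.5,
) -> SyntheticConfig:
    """Preset emulating the coral feeding-experiment study conditions.

    Host and symbiont are producer-like (TP 1, Glx-Phe spacing equal to
    beta = 3.4 permil); plankton is a consumer (TP 2, spacing 11.0
    permil), sits ``plankton_c_offset`` permil lower in d13C (on
    average; the per-AA pattern is :data:`PLANKTON_C_DEV`) and
    ``plankton_n_offset`` permil higher in d15N than the coral tissues.
    The d13C offsets are amino-acid specific so mean-normalized
    fingerprints remain group-separable.  Design: ``n_genets`` per
    treatment x 3 treatments x 2 tissue fractions, plus ``n_plankton``
    end-member samples; triplicate analytical noise of ``analytical_sd``
    permil per injection.
    """
    beta, delta = 3.4, 7.6
    tp = {"host": 1.0, "symbiont": 1.0, "plankton": 2.0}
    plank_shift = plankton_c_offset - (
        sum(PLANKTON_C_DEV[a] for a in MEASURED_13) / len(MEASURED_13)
    )
    c_dev = {
        "host": {aa: 0.0 for aa in MEASURED_13},
        "symbiont": SYMBIONT_C_DEV,
        "plankton": {aa: PLANKTON_C_DEV[aa] + plank_shift for aa in MEASURED_13},
    }
    n_dev = {
        "host": {aa: 0.0 for aa in MEASURED_13},
        "symbiont": SYMBIONT_N_DEV,
        "plankton": {aa: plankton_n_offset for aa in MEASURED_13},
    }
    means: dict[tuple[str, str], dict[str, float]] = {}
    for group in ("host", "symbiont", "plankton"):
        c_profile = {aa: HOST_D13C[aa] + c_dev[group][aa] for aa in MEASURED_13}
        n_profile = {aa: HOST_D15N[aa] + n_dev[group][aa] for aa in MEASURED_13}
        n_profile["Glx"] = _glx_from_tp(n_profile["Phe"], tp[group], beta, delta)
        means[(group, "C")] = c_profile
        means[(group, "N")] = n_profile
    return SyntheticConfig(
        aa_codes=list(MEASURED_13),
        means=means,
        tp_targets=tp,
        beta=beta,
        delta_tef=delta,
        analytical_sd={"C": analytical_sd, "N": analytical_sd},
        baseline_shift_sd=dict(baseline_shift_sd or {"C": 0.0, "N": 0.0}),
        n_genets=n_genets,
        n_plankton=n_plankton,
    )


def inject_trophic_shift(config: SyntheticConfig, group: str, delta_tp: float) -> SyntheticConfig:
    """Raise a group's trophic position by ``delta_tp`` steps.

    Shifts the group's latent Glx d15N mean by ``delta_tp * Delta``
    while leaving Phe untouched, and updates the recorded TP target.
    Returns a new config; the input is not modified.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}; have {config.groups}")
    out = config.copy()
    out.means[(group, "N")]["Glx"] += delta_tp * config.delta_tef
    out.tp_targets[group] = config.tp_targets.get(group, 1.0) + delta_tp
    return out


def generate_dataset(
    config: SyntheticConfig, seed: int
) -> tuple[AAIsotopeTable, GroundTruth]:
    """Draw one dataset: replicate injections collapsed to mean +/- sd.

    Deterministic given ``(config, seed)``.  Host and symbiont samples
    are generated per treatment x genet; plankton samples carry no
    treatment.  Per sample and element an optional common baseline
    shift is added to every amino acid before replicate noise.
    """
    rng = np.random.default_rng(seed)
    samples: list[tuple[str, str, str | None, str | None]] = []
    for fraction in ("host", "symbiont"):
        if fraction not in config.groups:
            continue
        for treatment in config.treatments:
            for g in range(1, config.n_genets + 1):
                sid = f"{fraction}-{treatment}-g{g}"
                samples.append((sid, fraction, treatment, f"g{g}"))
    if "plankton" in config.groups:
        for k in range(1, config.n_plankton + 1):
            samples.append((f"plankton-{k}", "plankton", None, None))

    rows = []
    for sid, fraction, treatment, genet in samples:
        shifts = {
            el: rng.normal(0.0, sd) if sd > 0 else 0.0
            for el, sd in config.baseline_shift_sd.items()
        }
        for element in ("C", "N"):
            profile = config.means.get((fraction, element))
            if profile is None:
                continue
            sd_an = config.analytical_sd[element]
            effects = config.treatment_effects.get((treatment, element), {}) if treatment else {}
            for aa in config.aa_codes:
                mu = profile[aa] + effects.get(aa, 0.0) + shifts.get(element, 0.0)
                reps = rng.normal(mu, sd_an, size=config.n_rep)
                rows.append(
                    {
                        "sample_id": sid,
                        "fraction": fraction,
                        "treatment": treatment,
                        "study": config.study,
                        "genet": genet,
                        "amino_acid": aa,
                        "element": element,
                        "delta": float(reps.mean()),
                        "sd": float(reps.std(ddof=1)),
                        "n_rep": config.n_rep,
                    }
                )
    table = AAIsotopeTable(pd.DataFrame(rows))
    truth = GroundTruth(
        means={f"{g}/{e}": dict(prof) for (g, e), prof in config.means.items()},
        tp_targets=dict(config.tp_targets),
        treatment_effects={
            f"{t}/{e}": dict(eff) for (t, e), eff in config.treatment_effects.items()
        },
        analytical_sd=dict(config.analytical_sd),
        seed=int(seed),
    )
    return table, truth
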