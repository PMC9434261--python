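"""Synthetic instrument- and assay-like data with known ground truth.

Every generator takes an explicit seed, draws from a single
``numpy.random.default_rng`` stream, and returns its dataset together with a
:class:`SimTruth` record of the generating parameters, so that any pipeline
stage can be tested by round-trip without real instrument output.

What is emulated (and what is not): TOF peak lists carry multiplicative
ppm-scale error with an optional systematic bias, probabilistic sodium-adduct
envelopes and uniform decoy peaks — but no isotopologue envelopes, peak
shapes or intensity model.  Assay data carry i.i.d. Gaussian noise on rates
(as a fraction of Vmax), and absorbance traces additive detector noise and
linear drift — but no coupled-enzyme lag or substrate depletion curvature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import PrecursorSpecies
from .ions import IonSpecies, MatchConfig, Peak, enumerate_ions
from .kinetics import (
    AssayConfig,
    AssayTrace,
    PHProfile,
    RateSeries,
    michaelis_menten,
    ph_bell,
    substrate_inhibition,
)

__all__ = [
    "SimTruth",
    "simulate_peaklist",
    "simulate_rate_series",
    "simulate_trace",
    "simulate_ph_profile",
]


@dataclass(frozen=True)
class SimTruth:
    """Seed plus generating parameters; serializable alongside the dataset."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "kind": self.kind, "params": self.params},
            sort_keys=True,
            default=str,
        )


def simulate_peaklist(
    species: Sequence[PrecursorSpecies],
    ppm_bias: float = 15.0,
    ppm_sigma: float = 5.0,
    base_ion_prob: float = 1.0,
    adduct_prob: float = 0.5,
    n_decoys: int = 0,
    seed: int = 0,
    cfg: "MatchConfig | None" = None,
) -> tuple[list[Peak], SimTruth]:
    """TOF-like peak list from known precursors.

    For each species the deprotonated (k=0) ions are included with
    probability ``base_ion_prob`` and sodium-adduct ions with
    ``adduct_prob``.  Observed m/z = theoretical * (1 + (bias + N(0, sigma))
    * 1e-6).  Decoys are drawn uniformly over the spanned m/z range while
    avoiding +/-3 sigma (in ppm) of every true ion.  Defaults mimic the
    instrument offsets of the reference peak table (+15 +/- 5 ppm).
    """
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    cfg = cfg or MatchConfig()
    ions = enumerate_ions(list(species), cfg)
    truth_ions: list[IonSpecies] = []
    peaks: list[Peak] = []
    for ion in ions:
        p = base_ion_prob if ion.k == 0 else adduct_prob
        if rng.random() < p:
            err_ppm = ppm_bias + rng.normal(0.0, ppm_sigma)
            peaks.append(Peak(mz=ion.mz * (1.0 + err_ppm * 1e-6)))
            truth_ions.append(ion)
    lo = min(i.mz for i in ions) * 0.9
    hi = max(i.mz for i in ions) * 1.1
    guard = 3.0 * max(ppm_sigma, 1.0) * 1e-6
    decoys: list[float] = []
    while len(decoys) < n_decoys:
        x = float(rng.uniform(lo, hi))
        if all(abs(x - i.mz) / i.mz > guard for i in ions):
            decoys.append(x)
            peaks.append(Peak(mz=x))
    truth = SimTruth(
        seed=seed,
        kind="peaklist",
        params=dict(
            species=[sp.identifier for sp in species],
            ppm_bias=ppm_bias,
            ppm_sigma=ppm_sigma,
            base_ion_prob=base_ion_prob,
            adduct_prob=adduct_prob,
            n_decoys=n_decoys,
            true_ions=[(i.parent.identifier, i.z, i.k) for i in truth_ions],
            decoys=decoys,
        ),
    )
    return peaks, truth


def simulate_rate_series(
    model: str,
    params: dict,
    s_grid: Sequence[float],
    sigma: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[RateSeries, SimTruth]:
    """Initial-rate data under 'MM' or 'SI' with N(0, (sigma*Vmax)^2) noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(list(s_grid), dtype=float)
    if s.size == 0:
        raise ValueError("S grid must be non-empty")
    if model == "MM":
        mean = michaelis_menten(s, params["vmax"], params["km"])
    elif model == "SI":
        mean = substrate_inhibition(s, params["vmax"], params["km"], params["ki"])
    else:
        raise ValueError(f"model must be 'MM' or 'SI', got {model!r}")
    rng = np.random.default_rng(seed)
    s_all = np.tile(s, replicates)
    rep = np.repeat(np.arange(replicates), s.size)
    v = np.tile(mean, replicates) + rng.normal(
        0.0, sigma * params["vmax"], size=s_all.size
    )
    truth = SimTruth(
        seed=seed,
        kind="rate_series",
        params=dict(model=model, sigma=sigma, replicates=replicates,
                    s_grid=list(map(float, s)), **params),
    )
    return RateSeries(s_um=s_all, v0=v, replicate=rep), truth


def simulate_trace(
    v0: float,
    config: AssayConfig,
    duration_s: float = 60.0,
    dt_s: float = 1.0,
    a0: float = 1.244,
    sigma_a: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTrace, SimTruth]:
    """A340 time course for a known v0, truncated at A340 >= 0.

    A340(t) = A0 - v0*[E]*eps*l*t + drift*t + N(0, sigma_a^2).  The default
    A0 corresponds to 0.2 mM NADH at eps = 6220 M^-1 cm^-1.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    slope = v0 * config.enzyme_m * config.epsilon * config.path_cm
    a = a0 - slope * t + drift * t
    if sigma_a > 0:
        a = a + rng.normal(0.0, sigma_a, size=t.size)
    a = np.maximum(a, 0.0)
    truth = SimTruth(
        seed=seed,
        kind="trace",
        params=dict(v0=v0, duration_s=duration_s, dt_s=dt_s, a0=a0,
                    sigma_a=sigma_a, drift=drift, enzyme_m=config.enzyme_m,
                    epsilon=config.epsilon, path_cm=config.path_cm),
    )
    return AssayTrace(time_s=t, a340=a, config=config), truth


def simulate_ph_profile(
    vopt: float,
    pka1: float,
    pka2: float,
    ph_grid: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[PHProfile, SimTruth]:
    """Diprotic bell values plus Gaussian noise (sigma as a fraction of vopt)."""
    if not pka1 < pka2:
        raise ValueError("pka1 must be < pka2")
    rng = np.random.default_rng(seed)
    ph = np.asarray(list(ph_grid), dtype=float)
    v = ph_bell(ph, vopt, pka1, pka2)
    if sigma > 0:
        v = v + rng.normal(0.0, sigma * vopt, size=ph.size)
    truth = SimTruth(
        seed=seed,
        kind="ph_profile",
        params=dict(vopt=vopt, pka1=pka1, pka2=pka2, sigma=sigma,
                    ph_grid=list(map(float, ph))),
    )
    return PHProfile(ph=ph, v0=v), truth
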