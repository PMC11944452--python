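"""Seeded simulator of study-like TGA / FT-IR / GC-MS data for HTL lignin.

The lab campaign this package targets measured depolymerized lignin at four
hydrothermal-liquefaction (HTL) anchor temperatures (250/300/350/400 °C):
one ~22,000-point thermogram per condition, three FT-IR transmittance
replicates on a fixed 3476-point wavenumber grid, and a 114-compound GC-MS
derivative table in nine groups whose detected totals fall short of 100%.
Those data are not publicly deposited, so this module generates data with
the same *statistical structure* at any HTL temperature in [240, 410] °C:

* TGA: ``mass(T) = 100 − Σ aᵢ(τ)·σ((T − cᵢ(τ))/wᵢ)`` — a moisture step, a
  main devolatilization step and a slow char step, each a logistic whose
  amplitude/center drift linearly in the normalized condition
  ``τ = (T_HTL − 250)/150``, over a residue plateau; plus Gaussian noise.
* FT-IR: baseline minus Gaussian absorption dips at standard lignin bands
  (O–H 3400, C–H 2930, C=O 1730, aromatic skeletal 1600/1510, 1215,
  1030 cm⁻¹) with τ-dependent depths; a slow baseline ripple plus noise
  lets some points exceed 100% transmittance, as real exports do.
* GC-MS: nine group fractions from a softmax of quadratic-in-τ logits,
  split over 114 derivative rows by fixed within-group geometric weights;
  a seeded subset of rows is flagged undetected so the detected total
  lands near ``100·(1 − u(τ))`` with u(τ) inside the configured range.

A :class:`GroundTruthOracle` exposes the *noiseless, processed* triplet at
any temperature — the reference for evaluating generators and the
predictor.  It is strictly an evaluation device, never training input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datatypes import (
    COMPOSITION_LABELS,
    GROUP_LABELS,
    CompositionVector,
    DerivativeRow,
    DerivativeTable,
    DomainError,
    IRPreprocessed,
    IRSpectrumRaw,
    SampleTriplet,
    ThermogramRaw,
    ThermogramResampled,
    ValidationError,
    ftir_wavenumber_grid,
)

__all__ = [
    "SimulatorParams",
    "GroundTruthOracle",
    "normalized_condition",
    "simulate_tga_raw",
    "simulate_ftir_replicates",
    "simulate_gcms_table",
    "simulate_study",
    "DEFAULT_ANCHOR_TEMPS",
]

DEFAULT_ANCHOR_TEMPS: tuple[float, ...] = (250.0, 300.0, 350.0, 400.0)

HTL_DOMAIN = (240.0, 410.0)


def normalized_condition(htl_temperature_c: float) -> float:
    """Map HTL temperature to τ = (T − 250)/150 (anchors span [0, 1])."""
    return (float(htl_temperature_c) - 250.0) / 150.0


# (amplitude_pct@τ=0, amplitude slope /τ, center_c@τ=0, center slope /τ, width_c)
_DEFAULT_TGA_STEPS: tuple[tuple[float, float, float, float, float], ...] = (
    (3.0, -1.0, 80.0, 0.0, 12.0),    # moisture release
    (35.0, 3.0, 330.0, 20.0, 35.0),  # main devolatilization
    (15.0, 0.0, 550.0, 10.0, 60.0),  # slow char-forming step
)

# (center cm^-1, width cm^-1, base depth %@τ=0, depth slope /τ)
_DEFAULT_FTIR_PEAKS: tuple[tuple[float, float, float, float], ...] = (
    (3400.0, 150.0, 25.0, 5.0),   # O-H stretch
    (2930.0, 40.0, 12.0, 3.0),    # C-H stretch
    (1730.0, 25.0, 18.0, -6.0),   # C=O stretch
    (1600.0, 30.0, 20.0, 4.0),    # aromatic skeletal
    (1510.0, 20.0, 18.0, -4.0),   # aromatic skeletal
    (1215.0, 40.0, 22.0, 3.0),    # C-O phenolic
    (1030.0, 50.0, 28.0, -5.0),   # C-O / aromatic C-H in-plane
)

# per-group (intercept, linear, quadratic) logit coefficients in τ;
# syringyl/guaiacyl decline and light fractions rise with temperature
_DEFAULT_GCMS_LOGITS: dict[str, tuple[float, float, float]] = {
    "Syringyl": (1.6, -1.2, 0.0),
    "Guaiacyl": (1.4, -0.8, 0.0),
    "PolyAromatics_C10_C21": (0.2, 2.0, -2.0),
    "OtherAromatics_C6_C20": (1.8, 0.5, 0.0),
    "Alkanes": (-1.2, 1.5, 0.0),
    "Cyclic": (-0.5, 0.3, 0.0),
    "FattyAcids": (-0.8, 0.6, 0.4),
    "Alcohol": (-1.6, 0.5, 0.0),
    "GlycerolDerived": (0.4, 0.8, -0.4),
}

_DEFAULT_DERIVS_PER_GROUP: dict[str, int] = {
    "Syringyl": 18,
    "Guaiacyl": 20,
    "PolyAromatics_C10_C21": 15,
    "OtherAromatics_C6_C20": 22,
    "Alkanes": 8,
    "Cyclic": 9,
    "FattyAcids": 8,
    "Alcohol": 6,
    "GlycerolDerived": 8,
}

# detection shortfall u(τ): deterministic quadratic spanning ~[0.088, 0.139],
# echoing detected totals of roughly 86-92% across the anchor range
_U_COEFFS = (0.088, 0.1675, -0.1365)


@dataclass
class SimulatorParams:
    """All knobs of the study simulator; defaults define the study conditions."""

    tga_steps: tuple[tuple[float, float, float, float, float], ...] = _DEFAULT_TGA_STEPS
    tga_residue_pct: float = 45.0
    tga_point_spacing_c: float = 0.034
    ftir_peaks: tuple[tuple[float, float, float, float], ...] = _DEFAULT_FTIR_PEAKS
    ftir_baseline_pct: float = 98.5
    ftir_ripple_pct: float = 1.0
    noise_sd_tga: float = 0.05
    noise_sd_ftir: float = 0.3
    gcms_logit_coeffs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GCMS_LOGITS)
    )
    derivatives_per_group: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_DERIVS_PER_GROUP)
    )
    undetected_fraction_range: tuple[float, float] = (0.08, 0.14)
    gcms_stochastic_detection: bool = True
    seed: int = 0

    def validate(self) -> None:
        for tau in (0.0, 1.0):
            amps = [a0 + a1 * tau for a0, a1, *_ in self.tga_steps]
            if any(a < 0 for a in amps):
                raise ValidationError("SimulatorParams.tga_steps: negative amplitude")
            if self.tga_residue_pct + sum(amps) > 100.0 + 1e-9:
                raise ValidationError(
                    "SimulatorParams: residue + step amplitudes exceed 100%"
                )
        for c, *_ in self.ftir_peaks:
            if not (650.0 <= c <= 4000.0):
                raise ValidationError(
                    f"SimulatorParams.ftir_peaks: center {c} outside [650, 4000]"
                )
        if sum(self.derivatives_per_group.values()) != 114:
            raise ValidationError(
                "SimulatorParams.derivatives_per_group: must sum to 114"
            )
        lo, hi = self.undetected_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValidationError("SimulatorParams.undetected_fraction_range: invalid")

    def noiseless(self) -> "SimulatorParams":
        """Copy with all stochastic components switched off."""
        return replace(
            self, noise_sd_tga=0.0, noise_sd_ftir=0.0, gcms_stochastic_detection=False
        )


def _check_domain(htl_temperature_c: float) -> None:
    lo, hi = HTL_DOMAIN
    if not (lo <= htl_temperature_c <= hi):
        raise DomainError(
            f"HTL temperature {htl_temperature_c} °C outside supported domain "
            f"[{lo}, {hi}]"
        )


def _tga_noiseless(temps: np.ndarray, tau: float, params: SimulatorParams) -> np.ndarray:
    mass = np.full_like(temps, 100.0)
    for a0, a1, c0, c1, w in params.tga_steps:
        amp = a0 + a1 * tau
        center = c0 + c1 * tau
        mass -= amp / (1.0 + np.exp(-(temps - center) / w))
    return mass


def _tga_grid(htl_temperature_c: float, params: SimulatorParams) -> np.ndarray:
    # start/end jitter mimics the instrument's per-run variability; it is a
    # deterministic function of the condition so the noiseless curve is
    # seed-independent
    phase = np.sin(htl_temperature_c * 12.9898)
    start = 39.6 + 0.4 * (0.5 + 0.5 * phase)
    end = 787.6 - 1.6 * (0.5 - 0.5 * phase)
    n = int(np.floor((end - start) / params.tga_point_spacing_c)) + 1
    return start + params.tga_point_spacing_c * np.arange(n)


def simulate_tga_raw(
    htl_temperature_c: float, params: SimulatorParams, seed: int
) -> ThermogramRaw:
    """Simulate one raw thermogram (~22,000 points, ~40-787 °C)."""
    _check_domain(htl_temperature_c)
    params.validate()
    tau = normalized_condition(htl_temperature_c)
    temps = _tga_grid(htl_temperature_c, params)
    mass = _tga_noiseless(temps, tau, params)
    if params.noise_sd_tga > 0:
        rng = np.random.default_rng(seed)
        mass = mass + rng.normal(0.0, params.noise_sd_tga, size=mass.shape)
    return ThermogramRaw(
        temperature_c=temps, mass_pct=mass, htl_temperature_c=htl_temperature_c
    )


def _ftir_noiseless(tau: float, params: SimulatorParams) -> np.ndarray:
    wn = ftir_wavenumber_grid()
    span = wn[-1] - wn[0]
    ripple = params.ftir_ripple_pct * np.sin(np.pi * (wn - wn[0]) / span) ** 2
    trans = params.ftir_baseline_pct + ripple
    for c, w, d0, d1 in params.ftir_peaks:
        depth = d0 + d1 * tau
        trans -= depth * np.exp(-0.5 * ((wn - c) / w) ** 2)
    return trans


def simulate_ftir_replicates(
    htl_temperature_c: float, params: SimulatorParams, seed: int
) -> list[IRSpectrumRaw]:
    """Simulate three FT-IR transmittance replicates on the canonical grid.

    Replicates share the noiseless spectrum and differ only in noise; with
    positive noise some points exceed 100% transmittance, exercising the
    clip branch of the downstream log preprocessing.
    """
    _check_domain(htl_temperature_c)
    params.validate()
    tau = normalized_condition(htl_temperature_c)
    base = _ftir_noiseless(tau, params)
    wn = ftir_wavenumber_grid()
    rng = np.random.default_rng(seed)
    out = []
    for rid in (1, 2, 3):
        trans = base.copy()
        if params.noise_sd_ftir > 0:
            trans = trans + rng.normal(0.0, params.noise_sd_ftir, size=trans.shape)
        out.append(
            IRSpectrumRaw(
                wavenumber_cm1=wn.copy(),
                transmittance_pct=trans,
                replicate_id=rid,
                htl_temperature_c=htl_temperature_c,
            )
        )
    return out


def _group_fractions(tau: float, params: SimulatorParams) -> np.ndarray:
    logits = np.array(
        [
            b0 + b1 * tau + b2 * tau * tau
            for b0, b1, b2 in (params.gcms_logit_coeffs[g] for g in GROUP_LABELS)
        ]
    )
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _undetected_fraction(tau: float, params: SimulatorParams) -> float:
    a, b, c = _U_COEFFS
    u = a + b * tau + c * tau * tau
    lo, hi = params.undetected_fraction_range
    if hi <= lo:  # degenerate range: detection is exact
        return float(lo)
    return float(np.clip(u, lo + 1e-6, hi - 1e-6))


def _within_group_weights(n: int) -> np.ndarray:
    w = 0.85 ** np.arange(n)
    return w / w.sum()


def simulate_gcms_table(
    htl_temperature_c: float, params: SimulatorParams, seed: int
) -> DerivativeTable:
    """Simulate a 114-row GC-MS derivative table with detection shortfall."""
    _check_domain(htl_temperature_c)
    params.validate()
    tau = normalized_condition(htl_temperature_c)
    fracs = _group_fractions(tau, params)
    u = _undetected_fraction(tau, params)

    names: list[str] = []
    groups: list[str] = []
    props: list[float] = []
    for g, frac in zip(GROUP_LABELS, fracs):
        n = params.derivatives_per_group[g]
        w = _within_group_weights(n)
        for k in range(n):
            names.append(f"{g}_{k + 1}")
            groups.append(g)
            props.append(100.0 * frac * w[k])
    props_arr = np.array(props)

    detected = np.ones(len(props), dtype=bool)
    if params.gcms_stochastic_detection:
        rng = np.random.default_rng(seed)
        target = 100.0 * u
        order = rng.permutation(len(props))
        flagged = 0.0
        for idx in order:
            if flagged + props_arr[idx] <= target:
                detected[idx] = False
                flagged += props_arr[idx]
    else:
        # exact proportional shortfall: scale every row, keep all detected
        props_arr = props_arr * (1.0 - u)

    rows = [
        DerivativeRow(
            compound_name=names[i],
            group=groups[i],
            proportion_pct=float(props_arr[i]),
            detected=bool(detected[i]),
        )
        for i in range(len(names))
    ]
    return DerivativeTable(rows=rows, htl_temperature_c=htl_temperature_c)


class GroundTruthOracle:
    """Noiseless processed triplet at any HTL temperature in the domain.

    Evaluation-only reference: the noiseless simulation is run and pushed
    through the standard preprocessing pipelines, so oracle vectors live on
    exactly the scales the models emit.  Seed-independent by construction.
    """

    def __init__(self, params: SimulatorParams) -> None:
        self.params = params.noiseless()

    def tga(self, htl_temperature_c: float) -> ThermogramResampled:
        from .preprocessing import PreprocessConfig, clip_resample_tga

        raw = simulate_tga_raw(htl_temperature_c, self.params, seed=0)
        return clip_resample_tga(raw, PreprocessConfig())

    def ftir(self, htl_temperature_c: float) -> IRPreprocessed:
        from .preprocessing import PreprocessConfig, preprocess_ftir

        reps = simulate_ftir_replicates(htl_temperature_c, self.params, seed=0)
        return preprocess_ftir(reps, PreprocessConfig())

    def composition(self, htl_temperature_c: float) -> CompositionVector:
        _check_domain(htl_temperature_c)
        tau = normalized_condition(htl_temperature_c)
        fracs9 = _group_fractions(tau, self.params)
        u = _undetected_fraction(tau, self.params)
        full = np.concatenate([fracs9 * (1.0 - u), [u]])
        return CompositionVector(full)

    def triplet(self, htl_temperature_c: float) -> SampleTriplet:
        return SampleTriplet(
            htl_temperature_c=float(htl_temperature_c),
            tga=self.tga(htl_temperature_c),
            ftir=self.ftir(htl_temperature_c),
            gcms=self.composition(htl_temperature_c),
        )


def simulate_study(
    anchor_temps: Sequence[float] | None = None,
    params: SimulatorParams | None = None,
    seed: int | None = None,
) -> tuple[dict, GroundTruthOracle]:
    """Simulate a full study bundle at the anchor temperatures.

    Returns ``(bundle, oracle)`` where bundle holds one thermogram, three
    FT-IR replicates and one derivative table per anchor (keys match
    :func:`lignosense.io.save_bundle`), and oracle is the noiseless
    ground-truth reference.
    """
    anchor_temps = list(DEFAULT_ANCHOR_TEMPS if anchor_temps is None else anchor_temps)
    if len(anchor_temps) < 2:
        raise ValidationError("simulate_study: need at least 2 anchor temperatures")
    params = SimulatorParams() if params is None else params
    params.validate()
    seed = params.seed if seed is None else int(seed)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * len(anchor_temps))
    bundle: dict = {"thermograms": [], "spectra": [], "gcms_tables": []}
    for i, temp in enumerate(anchor_temps):
        s_tga, s_ftir, s_gcms = (
            int(children[3 * i + j].generate_state(1)[0] % (2**31)) for j in range(3)
        )
        bundle["thermograms"].append(simulate_tga_raw(temp, params, s_tga))
        bundle["spectra"].extend(simulate_ftir_replicates(temp, params, s_ftir))
        bundle["gcms_tables"].append(simulate_gcms_table(temp, params, s_gcms))
    return bundle, GroundTruthOracle(params)
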