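"""Seeded synthetic ¹H/¹³C media spectra from ground-truth parameters.

The generator emulates the 1D NMR spectra of cell incubation media: citrate
¹³C multiplets whose positional intensities follow the forward Krebs-cycle
labeling model at a chosen (d, p, enrichment) ground truth, a ¹³C TSP
reference line at −2.0 ppm, remaining-glucose and ¹³C-lactate lines, and a
¹H spectrum with the citrate quartet, lactate/alanine methyl doublets with
¹³C satellites and the 0.2 mM TSP reference at 0 ppm.  Gaussian noise is
added per point at a configurable SNR (tallest citrate line height / noise
sigma).  Every output is a pure function of the ground truth, so the
generator doubles as the oracle for the quantification chain.

Multiplet fine structure (the C2 doublet fraction, the C3 five-line
pattern) is parameterized freely rather than derived: the positional model
tracks first moments only and carries no information about ¹³C-¹³C
co-labeling, so synthetic doublet fractions must not be over-interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import CitraceError, ModelRangeError, UndefinedRatioError
from .inversion import InversionResult, invert_ratios
from .model import ModelParams, TracerSpec, ratio_R1, ratio_R2, secreted_distribution
from .nmr.fitting import (
    fit_citrate_c24_region,
    fit_citrate_c3_region,
    fit_singlet,
)
from .nmr.quant import QuantConfig
from .nmr.spectrum import Spectrum1D, write_spectrum

__all__ = [
    "GroundTruth",
    "SyntheticExperiment",
    "RecoveryReport",
    "generate_experiment",
    "end_to_end_recovery",
    "write_experiment",
    "fixture_suite",
    "PPM_13C",
    "PPM_1H",
]

#: 13C chemical shifts (ppm) used by the generator.
PPM_13C = {
    "citrate_c24": 46.5,
    "citrate_c3": 76.2,
    "citrate_c15": 179.7,
    "citrate_c6": 181.8,
    "lactate_c3": 20.9,
    "glucose_c1": 96.7,
    "glucose_c6": 61.4,
    "tsp": -2.0,
}
#: 1H chemical shifts (ppm).
PPM_1H = {
    "citrate_quartet": (2.535, 2.57, 2.685, 2.72),
    "lactate_ch3": 1.33,
    "alanine_ch3": 1.48,
    "tsp": 0.0,
}

FREQ_1H_MHZ = 500.0
FREQ_13C_MHZ = 125.76
LW_13C_HZ = 8.0
LW_1H_HZ = 1.2
J_HH_HZ = 6.9
J_CH_HZ = 127.0
#: Arbitrary instrument response: integral units per mM per ¹H (or per ¹³C).
RESPONSE = 1000.0
GLUCOSE_TRACER_PURITY = 0.99


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth parameters for one synthetic incubation experiment."""

    d: float = 0.79
    p: float = 0.21
    tracer_id: str = "glucose_1_6"
    f_p: float = 0.80
    f_a: float = 0.56
    citrate_conc_mM: float = 0.27
    lactate_conc_mM: float = 5.0
    alanine_conc_mM: float = 0.5
    glucose_initial_mM: float = 11.0
    glucose_remaining_mM: float = 5.0
    doublet_fraction_c2: float = 0.30
    #: C3 multiplet pattern: (center, each ±19 Hz line, each ±38 Hz line).
    c3_pattern: tuple[float, float, float] = (0.6, 0.15, 0.05)
    #: Glutamine-run extras: reductive fraction of labeled citrate carbons,
    #: C6 attenuation and total labeled carbon concentration (mM).
    glutamine_reductive_fraction: float = 0.6
    c6_attenuation_lambda: float = 1.0
    glutamine_label_conc_mM: float = 0.2
    snr: float = 100.0
    seed: int = 0
    cfg: QuantConfig = field(
        default_factory=lambda: QuantConfig(medium_volume_mL=10.0, n_cells=10e6)
    )

    def tracer(self) -> TracerSpec:
        ctor = {
            "glucose_1_6": TracerSpec.glucose_1_6,
            "pyruvate_2": TracerSpec.pyruvate_2,
            "glutamine_5": TracerSpec.glutamine_5,
        }.get(self.tracer_id)
        if ctor is None:
            raise CitraceError(f"unknown tracer_id {self.tracer_id!r}")
        return ctor(f_p=self.f_p, f_a=self.f_a)


@dataclass(frozen=True)
class SyntheticExperiment:
    spectrum_1h: Spectrum1D
    spectrum_13c: Spectrum1D
    metadata: dict


def _add_line(intensity: np.ndarray, ppm_axis: np.ndarray, center_ppm: float,
              area: float, fwhm_hz: float, hz_per_ppm: float) -> float:
    """Add one absorption Lorentzian of the given analytic area; returns height."""
    if area <= 0:
        return 0.0
    height = 2.0 * area / (math.pi * fwhm_hz)
    hw = fwhm_hz / 2.0 / hz_per_ppm
    dx = ppm_axis - center_ppm
    intensity += height * hw * hw / (dx * dx + hw * hw)
    return height


def _citrate_13c_areas(truth: GroundTruth) -> dict[str, float]:
    """Analytic area for every citrate ¹³C line, keyed by line name."""
    scale = RESPONSE * truth.citrate_conc_mM
    if truth.tracer_id == "glutamine_5":
        f_red = truth.glutamine_reductive_fraction
        lam = truth.c6_attenuation_lambda
        total = RESPONSE * truth.glutamine_label_conc_mM
        # y + x + lam*x = total with y/(y+x+lam*x) = f_red
        y = f_red * total
        x = (total - y) / (1.0 + lam)
        return {"c15": y + x, "c6": lam * x}
    s = secreted_distribution(truth.tracer(), ModelParams(d=truth.d, p=truth.p))
    c24 = (s[2] + s[4]) * scale
    df = truth.doublet_fraction_c2
    f_c, f_19, f_38 = truth.c3_pattern
    c3 = s[3] * scale
    return {
        "c24_singlet": c24 * (1.0 - df),
        "c24_doublet_each": c24 * df / 2.0,
        "c3_center": c3 * f_c,
        "c3_p19_each": c3 * f_19,
        "c3_p38_each": c3 * f_38,
        "c15": (s[1] + s[5]) * scale,
        "c6": s[6] * scale,
    }


def generate_experiment(truth: GroundTruth) -> SyntheticExperiment:
    """Render the ¹H and ¹³C media spectra for one ground truth.

    Identical ground truths (including the seed) produce bit-identical
    spectra.
    """
    rng = np.random.default_rng(truth.seed)

    # --- 13C spectrum -----------------------------------------------------
    ppm_c = np.linspace(-5.0, 200.0, 32768)
    int_c = np.zeros_like(ppm_c)
    hzc = FREQ_13C_MHZ
    areas = _citrate_13c_areas(truth)
    j = 19.0 / hzc  # ppm displacement of the +-19 Hz lines
    heights = []
    if truth.tracer_id == "glutamine_5":
        heights.append(_add_line(int_c, ppm_c, PPM_13C["citrate_c15"], areas["c15"], LW_13C_HZ, hzc))
        heights.append(_add_line(int_c, ppm_c, PPM_13C["citrate_c6"], areas["c6"], LW_13C_HZ, hzc))
    else:
        a = PPM_13C["citrate_c24"]
        heights.append(_add_line(int_c, ppm_c, a, areas["c24_singlet"], LW_13C_HZ, hzc))
        heights.append(_add_line(int_c, ppm_c, a - j, areas["c24_doublet_each"], LW_13C_HZ, hzc))
        heights.append(_add_line(int_c, ppm_c, a + j, areas["c24_doublet_each"], LW_13C_HZ, hzc))
        a3 = PPM_13C["citrate_c3"]
        heights.append(_add_line(int_c, ppm_c, a3, areas["c3_center"], LW_13C_HZ, hzc))
        for sign in (-1, 1):
            heights.append(_add_line(int_c, ppm_c, a3 + sign * j, areas["c3_p19_each"], LW_13C_HZ, hzc))
            heights.append(_add_line(int_c, ppm_c, a3 + sign * 2 * j, areas["c3_p38_each"], LW_13C_HZ, hzc))
        heights.append(_add_line(int_c, ppm_c, PPM_13C["citrate_c15"], areas["c15"], LW_13C_HZ, hzc))
        heights.append(_add_line(int_c, ppm_c, PPM_13C["citrate_c6"], areas["c6"], LW_13C_HZ, hzc))
    # Non-citrate 13C lines: lactate C3, remaining glucose, TSP reference.
    _add_line(int_c, ppm_c, PPM_13C["lactate_c3"],
              RESPONSE * truth.lactate_conc_mM * truth.f_p, LW_13C_HZ, hzc)
    if truth.tracer_id == "glucose_1_6":
        per_carbon = RESPONSE * truth.glucose_remaining_mM * GLUCOSE_TRACER_PURITY
        _add_line(int_c, ppm_c, PPM_13C["glucose_c1"], per_carbon, LW_13C_HZ, hzc)
        _add_line(int_c, ppm_c, PPM_13C["glucose_c6"], per_carbon, LW_13C_HZ, hzc)
    _add_line(int_c, ppm_c, PPM_13C["tsp"], RESPONSE * 0.2 * 3.0, LW_13C_HZ, hzc)

    tallest_c = max([h for h in heights if h > 0], default=float(np.max(int_c)) or 1.0)
    sigma_c = tallest_c / truth.snr if tallest_c > 0 else 1.0 / truth.snr
    int_c = int_c + rng.normal(0.0, sigma_c, int_c.size)

    # --- 1H spectrum ------------------------------------------------------
    ppm_h = np.linspace(0.0 - 0.5, 10.0, 16384)
    int_h = np.zeros_like(ppm_h)
    hzh = FREQ_1H_MHZ
    cit_total = RESPONSE * truth.citrate_conc_mM * 4.0
    quartet_shares = (0.17, 0.33, 0.33, 0.17)
    h_heights = []
    for pos, share in zip(PPM_1H["citrate_quartet"], quartet_shares):
        h_heights.append(_add_line(int_h, ppm_h, pos, cit_total * share, LW_1H_HZ, hzh))
    for name, conc in (("lactate_ch3", truth.lactate_conc_mM),
                       ("alanine_ch3", truth.alanine_conc_mM)):
        center = PPM_1H[name]
        total = RESPONSE * conc * 3.0
        hh = (J_HH_HZ / 2.0) / hzh
        ch = (J_CH_HZ / 2.0) / hzh
        for sign in (-1, 1):
            _add_line(int_h, ppm_h, center + sign * hh,
                      total * (1.0 - truth.f_p) / 2.0, LW_1H_HZ, hzh)
            for s2 in (-1, 1):
                _add_line(int_h, ppm_h, center + sign * ch + s2 * hh,
                          total * truth.f_p / 4.0, LW_1H_HZ, hzh)
    _add_line(int_h, ppm_h, PPM_1H["tsp"], RESPONSE * truth.cfg.tsp_conc_mM * 9.0,
              LW_1H_HZ, hzh)

    tallest_h = max([h for h in h_heights if h > 0], default=float(np.max(int_h)) or 1.0)
    sigma_h = tallest_h / truth.snr if tallest_h > 0 else 1.0 / truth.snr
    int_h = int_h + rng.normal(0.0, sigma_h, int_h.size)

    metadata = {
        "tracer_id": truth.tracer_id,
        "d": truth.d,
        "p": truth.p,
        "f_p": truth.f_p,
        "f_a": truth.f_a,
        "citrate_conc_mM": truth.citrate_conc_mM,
        "lactate_conc_mM": truth.lactate_conc_mM,
        "alanine_conc_mM": truth.alanine_conc_mM,
        "glucose_initial_mM": truth.glucose_initial_mM,
        "glucose_remaining_mM": truth.glucose_remaining_mM,
        "doublet_fraction_c2": truth.doublet_fraction_c2,
        "snr": truth.snr,
        "seed": truth.seed,
        "noise_sigma_13C": sigma_c,
        "noise_sigma_1H": sigma_h,
        "response_per_mM": RESPONSE,
        "tsp_conc_mM": truth.cfg.tsp_conc_mM,
        "incubation_h": truth.cfg.incubation_h,
        "medium_volume_mL": truth.cfg.medium_volume_mL,
        "n_cells": truth.cfg.n_cells,
    }
    return SyntheticExperiment(
        spectrum_1h=Spectrum1D("1H", ppm_h, int_h, FREQ_1H_MHZ),
        spectrum_13c=Spectrum1D("13C", ppm_c, int_c, FREQ_13C_MHZ),
        metadata=metadata,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """End-to-end parameter recovery from paired synthetic tracer runs."""

    R1_truth: float
    R1_hat: float
    R2_truth: float
    R2_hat: float
    d_truth: float
    d_hat: float
    p_truth: float
    p_hat: float
    inversion: InversionResult | None

    @property
    def d_error(self) -> float:
        return abs(self.d_hat - self.d_truth)

    @property
    def p_error(self) -> float:
        return abs(self.p_hat - self.p_truth)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise CitraceError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def end_to_end_recovery(
    truth: GroundTruth,
    pyruvate_f_p: float = 0.83,
    pyruvate_f_a_over_f_p: float | None = None,
) -> RecoveryReport:
    """generate → fit → ratios → invert, reporting recovery of (d, p).

    ``truth`` describes the glucose-tracer run; a paired [2-¹³C]pyruvate run
    is simulated at the same (d, p) with the pyruvate-experiment enrichment
    convention (acetyl/pyruvate enrichment ratio carried over from the
    glucose run unless overridden).
    """
    if truth.tracer_id != "glucose_1_6":
        raise CitraceError("end_to_end_recovery starts from a glucose-tracer truth")
    ratio = (
        pyruvate_f_a_over_f_p
        if pyruvate_f_a_over_f_p is not None
        else truth.f_a / truth.f_p
    )
    pyr_truth = replace(
        truth,
        tracer_id="pyruvate_2",
        f_p=pyruvate_f_p,
        f_a=pyruvate_f_p * ratio,
        seed=truth.seed + 1,
    )

    glucose_tracer = truth.tracer()
    pyruvate_tracer = pyr_truth.tracer()
    params = ModelParams(d=truth.d, p=truth.p)
    r1_truth = ratio_R1(secreted_distribution(glucose_tracer, params))
    r2_truth = ratio_R2(secreted_distribution(pyruvate_tracer, params))

    with _stage("simulate"):
        glc_exp = generate_experiment(truth)
        pyr_exp = generate_experiment(pyr_truth)

    with _stage("fit_glucose_run"):
        # C2/4 must carry signal; C3 may legitimately be near zero (p -> 0),
        # so its fit is not signal-gated.
        c24 = fit_citrate_c24_region(glc_exp.spectrum_13c, require_signal=True)
        c3_glc = fit_citrate_c3_region(
            glc_exp.spectrum_13c,
            fixed_linewidth_hz=c24.linewidths_hz.get("lw"),
        )

    with _stage("fit_pyruvate_run"):
        c15 = fit_singlet(
            pyr_exp.spectrum_13c, PPM_13C["citrate_c15"], group="C1/5",
            require_signal=True,
        )
        c3_pyr = fit_citrate_c3_region(
            pyr_exp.spectrum_13c,
            fixed_linewidth_hz=c15.linewidths_hz.get("lw"),
        )

    with _stage("ratios"):
        c24_total = c24.total("C2/4")
        r1_hat = (c24_total - c3_glc.total("C3")) / c24_total
        c3_total = c3_pyr.total("C3")
        r2_hat = c15.total("C1/5") / c3_total if c3_total > 0 else math.inf

    # Degenerate truths (p ~ 0) push R2 outside the model envelope; the
    # report then carries the measured ratios with NaN parameter estimates.
    try:
        with _stage("invert"):
            inv = invert_ratios(
                r1_hat, r2_hat,
                glucose_tracer=glucose_tracer, pyruvate_tracer=pyruvate_tracer,
            )
        d_hat, p_hat = inv.d_hat, inv.p_hat
    except CitraceError as exc:
        if not isinstance(getattr(exc, "__cause__", None),
                          (ModelRangeError, UndefinedRatioError)) and not isinstance(
                              exc, (ModelRangeError, UndefinedRatioError)):
            raise
        inv = None
        d_hat = p_hat = float("nan")

    return RecoveryReport(
        R1_truth=r1_truth,
        R1_hat=r1_hat,
        R2_truth=r2_truth,
        R2_hat=r2_hat,
        d_truth=truth.d,
        d_hat=d_hat,
        p_truth=truth.p,
        p_hat=p_hat,
        inversion=inv,
    )


def write_experiment(
    exp: SyntheticExperiment, out_dir: str | Path, basename: str = "experiment"
) -> dict[str, Path]:
    """Write tabular spectra plus a YAML metadata sidecar to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectrum_1h": write_spectrum(exp.spectrum_1h, out / f"{basename}_1h.tsv"),
        "spectrum_13c": write_spectrum(exp.spectrum_13c, out / f"{basename}_13c.tsv"),
    }
    meta_path = out / f"{basename}_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(exp.metadata))
    paths["metadata"] = meta_path
    return paths


def fixture_suite(out_dir: str | Path, n: int = 12, base_seed: int = 1000) -> list[dict[str, Path]]:
    """Emit a standard suite of seeded experiments (alternating tracers)."""
    written = []
    for i in range(n):
        tracer = "glucose_1_6" if i % 2 == 0 else "pyruvate_2"
        f_p = 0.80 if tracer == "glucose_1_6" else 0.83
        f_a = 0.56 if tracer == "glucose_1_6" else 0.83 * 0.70
        truth = GroundTruth(tracer_id=tracer, f_p=f_p, f_a=f_a, seed=base_seed + i)
        exp = generate_experiment(truth)
        written.append(write_experiment(exp, Path(out_dir) / f"exp_{i:02d}"))
    return written
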