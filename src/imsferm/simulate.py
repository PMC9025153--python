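"""Synthetic HS-GC-IMS spectra of fermented dairy with ground truth.

The generator emulates the statistical structure of headspace GC-IMS
measurements of five fermented-dairy classes — commercial yogurt, commercial
kefir, two traditional mild kefir sub-varieties (LS, FN) and traditional
tangy kefir — each with a class-specific panel of volatile organic compounds
(VOCs):

* every class shares five compounds already present in milk at equal
  concentrations (ethanol, acetone, 2-butanone, 2-heptanone, 2-nonanone);
* yogurt adds diketones/ketones/acids typical of bacterial fermentation;
* commercial kefir resembles yogurt with acetoin elevated 3.5-fold, diacetyl
  reduced 2.3-fold and acetic acid newly present;
* traditional mild kefir carries a yeast-driven profile of alcohols, esters
  and aldehydes with strongly elevated ethanol (a saturating band more than
  100 s long); hexanal appears in the FN sub-variety only;
* tangy kefir intensifies the mild profile (alcohols x1.6, ethyl acetate
  x3.4, 3-methylbutanal x4) and adds three further compounds.

Peaks are Gaussian along drift and exponentially modified Gaussian along
retention (chromatographic tailing).  Each spectrum carries a reactant ion
peak (RIP) ridge depleted in proportion to local analyte intensity, a smooth
baseline, i.i.d. Gaussian noise, a per-spectrum drift-axis jitter, and an
amplitude-clipping ceiling reproducing ethanol saturation.  Retention centers
follow the measured compound table; drift positions without a published
RIP-relative value are synthetic, fixed fixture values.

Per-class microbial presence/absence over the 11 qPCR target taxa is emitted
alongside as ground truth for the microbe-VOC correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .preprocess import GCIMSSpectrum

__all__ = [
    "PeakSpec",
    "ClassPanel",
    "GeneratorConfig",
    "GroundTruth",
    "CLASS_LABELS",
    "MICROBES",
    "COMPOUND_TABLE",
    "default_panels",
    "render_spectrum",
    "render_class_pattern",
    "generate_dataset",
    "merge_mild",
]

CLASS_LABELS = ("yogurt", "commercial_kefir", "mild_LS", "mild_FN", "tangy")

#: The 11 qPCR target taxa screened in kefir microbiome panels.
MICROBES = (
    "Lb. kefiranofaciens",
    "Lb. kefiri",
    "Le. mesenteroides",
    "Lc. lactis",
    "Ac. orientalis",
    "Ac. fabarum",
    "S. cerevisiae",
    "Kl. marxianus",
    "Kz. turicensis",
    "Kz. unispora",
    "D. anomalous",
)

# Presence vectors per class.  Commercial kefir carries the two bacteria
# only; tangy adds the yeast Kl. marxianus; the mild sub-varieties are
# distinguished by D. anomalous (FN only, the suspected hexanal producer).
CLASS_MICROBES: dict[str, tuple[str, ...]] = {
    "yogurt": (),
    "commercial_kefir": ("Le. mesenteroides", "Lc. lactis"),
    "tangy": ("Le. mesenteroides", "Lc. lactis", "Kl. marxianus"),
    "mild_LS": ("Kz. unispora",),
    "mild_FN": ("Kz. unispora", "D. anomalous"),
}

# Peak-position fixture: retention start (s) from the measured compound
# table; Gaussian centers are placed 8 s after the printed start (the table
# reports where a peak begins, not its apex).  Drift positions are SYNTHETIC
# fixture values (only ethanol's 1.052 RIPrel monomer is a measured
# position); they are fixed, not fitted.
_RT_CENTER_OFFSET_S = 8.0

#: name -> (retention start s, drift position RIPrel, odor descriptor)
#: Synthetic drift positions are spaced so that no two compounds whose
#: retention peaks can touch (within ~54 s) have overlapping +/-3-sigma
#: integration windows, the way an analyst pre-selects peak areas.
COMPOUND_TABLE: dict[str, tuple[float, float, str]] = {
    "ethanol": (150.1, 1.052, "dry, dust"),
    "acetone": (155.6, 1.130, "earthy, fruity"),
    "2-methylpropanal": (167.6, 1.210, "faint gasoline-like"),
    "acetic acid": (169.9, 1.290, "vinegar, sour"),
    "diacetyl": (174.0, 1.370, "buttery, strong"),
    "2-butanone": (178.0, 1.450, "buttery, sour milk"),
    "ethyl acetate": (182.2, 1.530, "solvent, pineapple"),
    "2-methyl-1-propanol": (188.1, 1.610, "malty"),
    "3-methylbutanal": (198.7, 1.690, "malty, cocoa"),
    "2-methylbutanal": (203.3, 1.770, "malty, almond"),
    "2-pentanone": (214.2, 1.130, "orange peel, sweet"),
    "2,3-pentanedione": (216.3, 1.850, "creamy, buttery"),
    "acetoin": (226.7, 1.210, "bland, yogurt-like"),
    "methyl-1-butanol": (239.4, 1.290, "alcoholic, fruity"),
    "butyric acid": (264.3, 1.370, "unpleasant, rancid"),
    "hexanal": (286.3, 1.130, "green, grassy"),
    "3-methylbutyl acetate": (355.1, 1.470, "banana, candy"),
    "2-heptanone": (369.2, 1.260, "blue cheese"),
    "2-nonanone": (570.8, 1.340, "malty, hot milk"),
    "hexanoic acid": (443.7, 1.300, "sweaty, goaty"),
    "ethyl hexanoate": (474.0, 1.440, "fruity, apple"),
}

_DEFAULT_RT_SIGMA_S = 6.0
_DEFAULT_DT_SIGMA_RIPREL = 0.008


@dataclass(frozen=True)
class PeakSpec:
    """One compound peak: position, shape and amplitude.

    ``retention_tail`` is the exponential tail constant in units of
    ``retention_sigma`` (0 = symmetric Gaussian); ``drift_center`` and
    ``drift_sigma`` are RIP-relative.
    """

    compound_name: str
    retention_center: float
    retention_sigma: float
    drift_center: float
    drift_sigma: float
    amplitude: float
    retention_tail: float = 0.0

    def __post_init__(self) -> None:
        if self.retention_sigma <= 0 or self.drift_sigma <= 0:
            raise ValueError("peak sigmas must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.drift_center <= 1.0:
            raise ValueError(
                "analyte drift_center must exceed 1.0 RIPrel (analyte ions "
                "arrive after the RIP)"
            )
        if self.retention_tail < 0:
            raise ValueError("retention_tail must be >= 0")


@dataclass(frozen=True)
class ClassPanel:
    """A class label plus its compound peak panel."""

    label: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        names = [p.compound_name for p in self.peaks]
        if len(names) != len(set(names)):
            raise ValueError("duplicate compound in panel")

    def amplitude(self, compound: str) -> float:
        for p in self.peaks:
            if p.compound_name == compound:
                return p.amplitude
        return 0.0


def _peak(name: str, amplitude: float, *, tail: float = 0.0,
          rt_sigma: float = _DEFAULT_RT_SIGMA_S,
          dt_sigma: float = _DEFAULT_DT_SIGMA_RIPREL) -> PeakSpec:
    rt_start, drift, _ = COMPOUND_TABLE[name]
    return PeakSpec(
        compound_name=name,
        retention_center=rt_start + _RT_CENTER_OFFSET_S,
        retention_sigma=rt_sigma,
        drift_center=drift,
        drift_sigma=dt_sigma,
        amplitude=amplitude,
        retention_tail=tail,
    )


# Baseline amplitudes (arbitrary intensity units).
_MILK_ETHANOL = 150.0
_ELEVATED_ETHANOL = 1200.0   # saturating in traditional kefir
_ETHANOL_TAIL = 8.0          # tail constant: band stretches > 100 s
_ACETOIN_YOGURT = 80.0
_DIACETYL_YOGURT = 230.0
_ETHYL_ACETATE_MILD = 70.0
_METHYLBUTANAL_MILD = 40.0
_ALCOHOL_MILD = {"2-methyl-1-propanol": 90.0, "methyl-1-butanol": 110.0}


def default_panels() -> dict[str, ClassPanel]:
    """Class panels with the fold-change structure of the study classes.

    Commercial kefir / yogurt acetoin ratio is 3.5 and diacetyl 1/2.3;
    tangy / mild ratios are 3.4 (ethyl acetate), 4 (3-methylbutanal) and 1.6
    (the two non-ethanol alcohols); hexanal occurs in mild_FN only.
    """
    milk_shared = [
        _peak("ethanol", _MILK_ETHANOL, tail=_ETHANOL_TAIL, dt_sigma=0.010),
        _peak("acetone", 120.0),
        _peak("2-butanone", 110.0),
        _peak("2-heptanone", 90.0),
        _peak("2-nonanone", 80.0),
    ]
    yogurt = milk_shared + [
        _peak("diacetyl", _DIACETYL_YOGURT),
        _peak("2,3-pentanedione", 100.0),
        _peak("2-pentanone", 90.0),
        _peak("acetoin", _ACETOIN_YOGURT),
        _peak("butyric acid", 70.0),
        _peak("hexanoic acid", 60.0),
    ]
    commercial = [
        p for p in yogurt
        if p.compound_name not in ("2,3-pentanedione", "2-pentanone")
    ]
    commercial = [
        replace(p, amplitude=_ACETOIN_YOGURT * 3.5)
        if p.compound_name == "acetoin"
        else replace(p, amplitude=_DIACETYL_YOGURT / 2.3)
        if p.compound_name == "diacetyl"
        else p
        for p in commercial
    ] + [_peak("acetic acid", 160.0)]
    mild_base = [
        replace(p, amplitude=_ELEVATED_ETHANOL)
        if p.compound_name == "ethanol"
        else p
        for p in milk_shared
        if p.compound_name != "2-butanone"
    ] + [
        _peak("2-methyl-1-propanol", _ALCOHOL_MILD["2-methyl-1-propanol"]),
        _peak("methyl-1-butanol", _ALCOHOL_MILD["methyl-1-butanol"]),
        _peak("ethyl acetate", _ETHYL_ACETATE_MILD),
        _peak("ethyl hexanoate", 60.0),
        _peak("3-methylbutanal", _METHYLBUTANAL_MILD),
    ]
    mild_fn = mild_base + [_peak("hexanal", 80.0)]
    tangy = [
        replace(p, amplitude=p.amplitude * 1.6)
        if p.compound_name in _ALCOHOL_MILD
        else replace(p, amplitude=p.amplitude * 3.4)
        if p.compound_name == "ethyl acetate"
        else replace(p, amplitude=p.amplitude * 4.0)
        if p.compound_name == "3-methylbutanal"
        else p
        for p in mild_base
    ] + [
        _peak("3-methylbutyl acetate", 100.0),
        _peak("2-methylbutanal", 70.0),
        _peak("2-methylpropanal", 60.0),
    ]
    return {
        "yogurt": ClassPanel("yogurt", tuple(yogurt)),
        "commercial_kefir": ClassPanel("commercial_kefir", tuple(commercial)),
        "mild_LS": ClassPanel("mild_LS", tuple(mild_base)),
        "mild_FN": ClassPanel("mild_FN", tuple(mild_fn)),
        "tangy": ClassPanel("tangy", tuple(tangy)),
    }


def _default_retention_axis() -> np.ndarray:
    return np.arange(99.0, 620.0 + 1e-9, 1.2)


def _default_drift_axis() -> np.ndarray:
    return np.arange(7.0, 15.2, 0.018)


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition and noise model of the simulated instrument.

    Duplicate headspace measurements per sample (default 2) reflect the
    study design; noise, baseline, RIP depletion and drift jitter magnitudes
    are synthetic defaults chosen to sit well below the analyte peak
    amplitudes (tens to hundreds of intensity units).
    """

    samples_per_class: int = 16
    duplicates_per_sample: int = 2
    retention_axis: np.ndarray = field(default_factory=_default_retention_axis)
    drift_axis: np.ndarray = field(default_factory=_default_drift_axis)
    rip_drift_time: float = 7.5       # ms
    rip_amplitude: float = 1200.0
    rip_width_ms: float = 0.08
    depletion_fraction: float = 0.3
    baseline_drift_amplitude: float = 15.0
    noise_sd: float = 2.0
    drift_jitter_sd: float = 0.02     # ms
    amplitude_cv: float = 0.10        # lognormal between-sample variation
    saturation_ceiling: float = 350.0  # intensity clip (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "retention_axis", np.asarray(self.retention_axis, float)
        )
        object.__setattr__(
            self, "drift_axis", np.asarray(self.drift_axis, float)
        )
        for name in ("retention_axis", "drift_axis"):
            if not np.all(np.diff(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not 0.0 <= self.depletion_fraction <= 1.0:
            raise ValueError("depletion_fraction must be in [0, 1]")
        if self.duplicates_per_sample < 1:
            raise ValueError("duplicates_per_sample must be >= 1")


@dataclass
class SampleTruth:
    """True per-sample state: label, sub-variety and compound amplitudes."""

    sample_id: str
    class_label: str
    sub_variety: str
    amplitudes: dict[str, float]


@dataclass
class GroundTruth:
    """Everything the recovery tests need to score the pipeline."""

    samples: list[SampleTruth]
    positions: dict[str, tuple[float, float]]  # name -> (rt center s, RIPrel)
    class_microbes: dict[str, tuple[str, ...]]
    panels: dict[str, ClassPanel]

    def microbe_table(self) -> pd.DataFrame:
        """Per-sample presence (0/1) over the 11 qPCR taxa."""
        rows = {
            s.sample_id: {
                m: int(m in self.class_microbes[s.class_label])
                for m in MICROBES
            }
            for s in self.samples
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(MICROBES)]

    def labels(self, sample_ids: list[str]) -> list[str]:
        lut = {s.sample_id: s.class_label for s in self.samples}
        return [lut[sid] for sid in sample_ids]


def merge_mild(labels: list[str]) -> list[str]:
    """Collapse the two mild sub-varieties into one 'mild' class (4 labels)."""
    return ["mild" if lab.startswith("mild") else lab for lab in labels]


def _retention_profile(peak: PeakSpec, rt: np.ndarray) -> np.ndarray:
    """Retention profile scaled so its integral is amp * sigma * sqrt(2pi)."""
    if peak.retention_tail == 0.0:
        return peak.amplitude * np.exp(
            -0.5 * ((rt - peak.retention_center) / peak.retention_sigma) ** 2
        )
    k = peak.retention_tail  # tau / sigma
    pdf = exponnorm.pdf(
        rt, K=k, loc=peak.retention_center, scale=peak.retention_sigma
    )
    area = peak.amplitude * peak.retention_sigma * np.sqrt(2.0 * np.pi)
    return area * pdf


def _check_resolution(peak: PeakSpec, config: GeneratorConfig) -> None:
    rt_step = np.median(np.diff(config.retention_axis))
    dt_step = np.median(np.diff(config.drift_axis))
    if peak.retention_sigma / rt_step < 3.0:
        raise ValueError(
            f"retention axis too coarse for {peak.compound_name}: "
            f"{peak.retention_sigma / rt_step:.2f} grid points per sigma (< 3)"
        )
    dt_sigma_ms = peak.drift_sigma * config.rip_drift_time
    if dt_sigma_ms / dt_step < 3.0:
        raise ValueError(
            f"drift axis too coarse for {peak.compound_name}: "
            f"{dt_sigma_ms / dt_step:.2f} grid points per sigma (< 3)"
        )


def _analyte_map(
    peaks: tuple[PeakSpec, ...],
    rt: np.ndarray,
    dt_ms: np.ndarray,
    rip_ms: float,
) -> np.ndarray:
    out = np.zeros((rt.size, dt_ms.size))
    for peak in peaks:
        if peak.amplitude == 0.0:
            continue
        center_ms = peak.drift_center * rip_ms
        sigma_ms = peak.drift_sigma * rip_ms
        drift_profile = np.exp(-0.5 * ((dt_ms - center_ms) / sigma_ms) ** 2)
        out += np.outer(_retention_profile(peak, rt), drift_profile)
    return out


def render_spectrum(
    panel: ClassPanel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    replicate_id: str = "a",
    baseline_phases: tuple[float, float] | None = None,
) -> GCIMSSpectrum:
    """Forward model: analyte peaks + depleted RIP + baseline + noise.

    The analyte sum is clipped at ``saturation_ceiling`` (ethanol saturation),
    the RIP ridge is locally depleted in proportion to analyte intensity, and
    the drift axis is shifted by a per-spectrum jitter draw.
    """
    for peak in panel.peaks:
        _check_resolution(peak, config)
    rt = config.retention_axis
    dt = config.drift_axis
    jitter = (
        rng.normal(0.0, config.drift_jitter_sd)
        if config.drift_jitter_sd > 0
        else 0.0
    )
    analyte = _analyte_map(panel.peaks, rt, dt, config.rip_drift_time)
    if config.saturation_ceiling > 0:
        np.clip(analyte, None, config.saturation_ceiling, out=analyte)
    # RIP ridge, depleted where analyte signal is strong.
    rip_profile = np.exp(
        -0.5 * ((dt - config.rip_drift_time) / config.rip_width_ms) ** 2
    )
    global_max = analyte.max()
    row_max = analyte.max(axis=1)
    depletion = (
        config.depletion_fraction * row_max / global_max
        if global_max > 0
        else np.zeros_like(row_max)
    )
    rip_amp = config.rip_amplitude * (1.0 - depletion)
    intensity = analyte + np.outer(rip_amp, rip_profile)
    if config.baseline_drift_amplitude > 0:
        # phases are a per-sample property (same vial, same column bleed);
        # generate_dataset passes them so duplicates share one baseline
        ph = (
            np.asarray(baseline_phases)
            if baseline_phases is not None
            else rng.uniform(0.0, 2.0 * np.pi, size=2)
        )
        rt_wave = 0.6 + 0.4 * np.sin(
            2.0 * np.pi * (rt - rt[0]) / (rt[-1] - rt[0]) + ph[0]
        )
        dt_wave = 0.6 + 0.4 * np.sin(
            2.0 * np.pi * (dt - dt[0]) / (dt[-1] - dt[0]) + ph[1]
        )
        intensity += config.baseline_drift_amplitude * np.outer(
            rt_wave, dt_wave
        )
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, config.noise_sd, size=intensity.shape
        )
    return GCIMSSpectrum(
        sample_id=sample_id,
        replicate_id=replicate_id,
        intensity=np.clip(intensity, 0.0, None),
        retention_axis=rt.copy(),
        drift_axis=dt + jitter,
        class_label=panel.label,
        drift_units="ms",
        metadata={"rip_drift_time_true": config.rip_drift_time + jitter},
    )


def render_class_pattern(
    panel: ClassPanel,
    retention_axis: np.ndarray,
    riprel_axis: np.ndarray,
    saturation_ceiling: float = 0.0,
) -> np.ndarray:
    """Noise-free analyte-only pattern directly on a RIPrel grid.

    The reference a recovered decomposition component is compared against.
    """
    out = np.zeros((retention_axis.size, riprel_axis.size))
    for peak in panel.peaks:
        drift_profile = np.exp(
            -0.5 * ((riprel_axis - peak.drift_center) / peak.drift_sigma) ** 2
        )
        out += np.outer(
            _retention_profile(peak, retention_axis), drift_profile
        )
    if saturation_ceiling > 0:
        np.clip(out, None, saturation_ceiling, out=out)
    return out


def generate_dataset(
    config: GeneratorConfig,
    panels: dict[str, ClassPanel] | None = None,
) -> tuple[list[GCIMSSpectrum], GroundTruth]:
    """Generate the full raw spectrum collection plus ground truth.

    Yields ``samples_per_class`` samples for each of the five classes, each
    measured ``duplicates_per_sample`` times.  Between-sample concentration
    variability is lognormal with CV ``amplitude_cv``; duplicates share a
    sample's true amplitudes and differ only in noise, baseline and jitter.
    Identical seeds give bit-identical output.
    """
    if config.samples_per_class < 2:
        raise ValueError(
            "samples_per_class must be >= 2 (cross-validation downstream)"
        )
    panels = panels or default_panels()
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log(1.0 + config.amplitude_cv**2))
    spectra: list[GCIMSSpectrum] = []
    truths: list[SampleTruth] = []
    for label in CLASS_LABELS:
        panel = panels[label]
        for i in range(config.samples_per_class):
            sample_id = f"{label}-{i:02d}"
            if config.amplitude_cv > 0:
                factors = rng.lognormal(
                    -0.5 * sigma**2, sigma, size=len(panel.peaks)
                )
            else:
                factors = np.ones(len(panel.peaks))
            sample_panel = ClassPanel(
                label,
                tuple(
                    replace(p, amplitude=p.amplitude * f)
                    for p, f in zip(panel.peaks, factors)
                ),
            )
            truths.append(
                SampleTruth(
                    sample_id=sample_id,
                    class_label=label,
                    sub_variety=label.split("_")[-1] if "_" in label else "",
                    amplitudes={
                        p.compound_name: p.amplitude for p in sample_panel.peaks
                    },
                )
            )
            phases = tuple(rng.uniform(0.0, 2.0 * np.pi, size=2))
            for r in range(config.duplicates_per_sample):
                spectra.append(
                    render_spectrum(
                        sample_panel,
                        config,
                        rng,
                        sample_id=sample_id,
                        replicate_id=chr(ord("a") + r),
                        baseline_phases=phases,
                    )
                )
    positions = {
        name: (rt + _RT_CENTER_OFFSET_S, drift)
        for name, (rt, drift, _) in COMPOUND_TABLE.items()
    }
    truth = GroundTruth(
        samples=truths,
        positions=positions,
        class_microbes=dict(CLASS_MICROBES),
        panels=panels,
    )
    return spectra, truth
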