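"""Ground-truthed phantoms: gelatine standard blocks and tissue sections.

No raw clinical ablation data is available, so every stage of the pipeline
is validated on synthetic phantoms that reproduce the statistical structure
the analysis assumes:

* calibration-standard blocks (default 5 lines x 200 pixels) spanning
  0-33 ug/g for Fe and 0-19 ug/g for Cu, Zn and Sr, with Poisson counting
  noise and a cross-quantification error on the measured concentrations;
* tissue sections on a glass slide: an elliptical section containing
  low-signal adipose blobs and a high-signal epithelial (lesion) area,
  optionally split into tumor niche and stroma, with Fe hot spots in
  metastatic samples, sparse salt-spike noise and Poisson counting noise;
* H / NM / M cohorts whose per-sample epithelial medians follow the
  configured group distributions, so group-level statistics are testable
  end to end.

Concentration fields are lognormal (positive, right-skewed; the simplest
law matching a median with asymmetric quartiles); Sr and Ba share a
Gaussian copula with a configurable rank correlation.  Counting noise is
Poisson on expected counts (cps x dwell), converted back to cps, so SNR
scales with concentration as in real ablation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import StandardMeasurement
from .imaging import (DEFAULT_LEGEND, AcquisitionMeta, ElementImage,
                      ImageStack, RegionAnnotation, SampleRecord)

Z75 = float(norm.ppf(0.75))  # 0.6744897...

#: Default per-group epithelial concentration spec, ug/g, as (median, q1, q3)
#: of the per-sample median distribution.  Ba is expressed in Sr-equivalent
#: ug/g (response-factor normalized); its NM entry and all adipose Ba values
#: are generator choices, the rest follow reported breast-tissue cohorts.
GROUP_CONC: dict[str, dict[str, tuple[float, float, float]]] = {
    "56Fe": {"H": (2.9, 0.9, 4.4), "NM": (12.6, 5.2, 26.1), "M": (6.6, 4.1, 34.1)},
    "63Cu": {"H": (0.04, 0.03, 0.06), "NM": (0.06, 0.05, 0.20), "M": (0.07, 0.05, 0.20)},
    "66Zn": {"H": (0.12, 0.08, 0.30), "NM": (0.78, 0.50, 0.93), "M": (0.63, 0.30, 1.14)},
    "88Sr": {"H": (0.5, 0.4, 0.8), "NM": (1.8, 1.2, 3.0), "M": (1.4, 0.8, 2.8)},
    "138Ba": {"H": (0.05, 0.04, 0.14), "NM": (0.12, 0.06, 0.25), "M": (0.20, 0.10, 0.31)},
}

#: Adipose-tissue concentration spec (group-independent), ug/g.
ADIPOSE_CONC: dict[str, tuple[float, float, float]] = {
    "56Fe": (0.79, 0.46, 1.26),
    "63Cu": (0.03, 0.01, 0.06),
    "66Zn": (0.06, 0.02, 0.19),
    "88Sr": (0.13, 0.08, 0.18),
    "138Ba": (0.02, 0.01, 0.04),
}

#: Instrument sensitivity per element: (slope cps per ug/g, intercept cps).
SENSITIVITY: dict[str, tuple[float, float]] = {
    "56Fe": (2.0e4, 20.0),
    "63Cu": (3.0e5, 15.0),
    "66Zn": (1.5e5, 25.0),
    "88Sr": (8.0e4, 10.0),
    "138Ba": (8.0e4, 10.0),
}

#: Default calibration standard concentrations, ug/g.
STANDARD_CONCS: dict[str, tuple[float, ...]] = {
    "56Fe": (0.0, 2.0, 8.0, 16.0, 33.0),
    "63Cu": (0.0, 2.0, 5.0, 10.0, 19.0),
    "66Zn": (0.0, 2.0, 5.0, 10.0, 19.0),
    "88Sr": (0.0, 2.0, 5.0, 10.0, 19.0),
}

SR_REFERENCE_CONC = 1.31  # ug/g, the spiked Sr standard used for Ba

#: Default tumor-niche / stroma concentration ratio per element.  Cu, Zn,
#: Sr (and Ba) run higher in the niche; Fe is heterogeneous with no
#: consistent niche excess.  Applied symmetrically (niche x sqrt(ratio),
#: stroma / sqrt(ratio)) so the epithelial geometric mean is preserved.
NICHE_STROMA_RATIO: dict[str, float] = {
    "56Fe": 1.0,
    "63Cu": 1.6,
    "66Zn": 1.8,
    "88Sr": 1.5,
    "138Ba": 1.4,
}


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and quartile ratio.

    sigma = ln(q3/q1) / (2 z_0.75) is exact for a lognormal; the configured
    median fixes mu.
    """
    if median <= 0 or q1 <= 0:
        raise ValueError("median and quartiles must be positive")
    if q3 <= q1:
        raise ValueError(f"infeasible quartiles: q3 ({q3}) must exceed q1 ({q1})")
    return float(np.log(median)), float(np.log(q3 / q1) / (2 * Z75))


@dataclass
class GeometrySpec:
    """Procedural section geometry (ellipses and discs; the pipeline
    consumes labels, not morphology)."""

    tissue_axes: tuple[float, float] = (0.42, 0.44)  # fractions of image size
    adipose_blobs: int = 4
    adipose_radius_frac: float = 0.07
    tumor_niche_frac: float = 0.35   # target fraction of the epithelium
    hotspot_count: int = 3
    hotspot_radius: int = 3
    hotspot_amplitude: float = 8.0
    hotspot_element: str = "56Fe"
    hotspot_groups: tuple[str, ...] = ("M",)


@dataclass
class NoiseSpec:
    """Forward-model noise: Poisson counting noise on expected counts,
    sparse multiplicative salt spikes, and a Gaussian glass-background
    intensity for off-tissue pixels."""

    poisson: bool = True
    spike_prob: float = 5e-4
    spike_factor: float = 30.0
    glass_level: float = 50.0   # cps
    glass_sd: float = 15.0      # cps
    cross_quant_cv: float = 0.02


@dataclass
class PhantomConfig:
    shape: tuple[int, int] = (120, 160)
    seed: int = 0
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    conc: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {e: dict(g) for e, g in GROUP_CONC.items()})
    adipose_conc: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(ADIPOSE_CONC))
    sensitivity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SENSITIVITY))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sr_ba_rank_correlation: float = 0.90
    between_sample_sigma: float = 0.6  # lognormal sigma of per-sample median multipliers
    field_smooth_sigma: float = 0.0    # px; >0 gives spatially coherent fields
    niche_stroma_ratio: dict[str, float] = field(
        default_factory=lambda: dict(NICHE_STROMA_RATIO))
    meta: AcquisitionMeta = field(default_factory=lambda: AcquisitionMeta(
        isotopes=list(GROUP_CONC)))

    def __post_init__(self) -> None:
        if not -1 <= self.sr_ba_rank_correlation <= 1:
            raise ValueError("sr_ba_rank_correlation must lie in [-1, 1]")
        for el, groups in self.conc.items():
            for g, (m, q1, q3) in groups.items():
                lognormal_params(m, q1, q3)  # validates feasibility
        self.meta = replace(self.meta, isotopes=list(self.conc))

    @property
    def elements(self) -> list[str]:
        return list(self.conc)


@dataclass
class SyntheticPhantom:
    stack: ImageStack
    truth_conc: dict[str, np.ndarray]
    annotation: RegionAnnotation
    config: PhantomConfig


# ---------------------------------------------------------------------------
# Standards
# ---------------------------------------------------------------------------

def generate_standard_block(element: str, conc: float, slope: float,
                            intercept: float, n_lines: int = 5,
                            n_pixels: int = 200, seed: int = 0,
                            noise: bool = True, cross_quant_cv: float = 0.02,
                            dwell_ms: float = 23.0) -> StandardMeasurement:
    """Simulate the ablation of one gelatine standard block.

    The true standard concentration deviates from the nominal spike by a
    relative preparation error of ``cross_quant_cv``; the digestion
    cross-quantification recovers that true value (which is why it is done),
    so ``measured_conc`` is the concentration the intensities were actually
    generated from.  Line intensities are Poisson(cps x dwell) / dwell
    around the expected response slope*true_conc + intercept.
    """
    if conc < 0:
        raise ValueError("conc must be nonnegative")
    rng = np.random.default_rng(seed)
    dwell_s = dwell_ms / 1000.0
    if noise:
        true_conc = conc * max(0.0, 1.0 + cross_quant_cv * rng.standard_normal())
        counts = rng.poisson((slope * true_conc + intercept) * dwell_s,
                             size=(n_lines, n_pixels))
        lines = counts / dwell_s
        measured = true_conc
    else:
        lines = np.full((n_lines, n_pixels), slope * conc + intercept)
        measured = conc
    return StandardMeasurement(element=element, nominal_conc=conc,
                               measured_conc=measured,
                               lines=[lines[i] for i in range(n_lines)])


def generate_standard_set(element: str, config: PhantomConfig | None = None,
                          concs: Sequence[float] | None = None,
                          seed: int = 0, noise: bool = True) -> list[StandardMeasurement]:
    """A full calibration series for one element (blank included)."""
    if config is None:
        config = PhantomConfig()
    if concs is None:
        concs = STANDARD_CONCS.get(element, (0.0, 2.0, 5.0, 10.0, 19.0))
    slope, intercept = config.sensitivity[element]
    rng = np.random.default_rng(seed)
    return [generate_standard_block(element, c, slope, intercept,
                                    seed=int(rng.integers(2**31)), noise=noise,
                                    cross_quant_cv=config.noise.cross_quant_cv,
                                    dwell_ms=config.meta.dwell_ms)
            for c in concs]


def generate_sr_reference(config: PhantomConfig | None = None, seed: int = 0,
                          noise: bool = True) -> StandardMeasurement:
    """The spiked Sr gelatine standard (1.31 ug/g) used to normalize Ba."""
    if config is None:
        config = PhantomConfig()
    slope, intercept = config.sensitivity["88Sr"]
    return generate_standard_block("88Sr", SR_REFERENCE_CONC, slope, intercept,
                                   seed=seed, noise=noise,
                                   cross_quant_cv=config.noise.cross_quant_cv,
                                   dwell_ms=config.meta.dwell_ms)


# ---------------------------------------------------------------------------
# Tissue phantoms
# ---------------------------------------------------------------------------

def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _build_labels(config: PhantomConfig, group: str, include_stroma: bool,
                  rng: np.random.Generator) -> np.ndarray:
    nr, nc = config.shape
    geo = config.geometry
    rr, cc = np.ogrid[:nr, :nc]
    ar, ac = geo.tissue_axes[0] * nr, geo.tissue_axes[1] * nc
    tissue = ((rr - nr / 2) / ar) ** 2 + ((cc - nc / 2) / ac) ** 2 <= 1.0

    adipose = np.zeros_like(tissue)
    radius = geo.adipose_radius_frac * min(nr, nc)
    for _ in range(geo.adipose_blobs):
        center = (nr / 2 + (rng.uniform(-0.7, 0.7)) * ar,
                  nc / 2 + (rng.uniform(-0.7, 0.7)) * ac)
        adipose |= _disc((nr, nc), center, radius)
    adipose &= tissue
    epithelium = tissue & ~adipose

    labels = np.zeros((nr, nc), dtype=int)
    labels[adipose] = 1
    if group == "H":
        labels[epithelium] = 2
        return labels
    if include_stroma:
        # central ellipse scaled to hit the configured tumor-niche fraction
        scale = np.sqrt(geo.tumor_niche_frac)
        niche = ((rr - nr / 2) / (scale * ar)) ** 2 + \
            ((cc - nc / 2) / (scale * ac)) ** 2 <= 1.0
        niche &= epithelium
        labels[epithelium] = 4     # stroma
        labels[niche] = 3          # tumor niche
    else:
        labels[epithelium] = 3     # cancer widespread: all tumor niche
    return labels


def _unit_normal_field(rng: np.random.Generator, shape: tuple[int, int],
                       smooth_sigma: float) -> np.ndarray:
    """White or (optionally) spatially smoothed unit-variance normal field."""
    z = rng.standard_normal(shape)
    if smooth_sigma <= 0:
        return z
    from scipy.ndimage import gaussian_filter

    sm = gaussian_filter(z, smooth_sigma, mode="reflect")
    n = int(8 * smooth_sigma) + 9
    impulse = np.zeros((n, n))
    impulse[n // 2, n // 2] = 1.0
    kernel = gaussian_filter(impulse, smooth_sigma, mode="constant")
    return sm / np.sqrt((kernel**2).sum())


def generate_tissue_phantom(config: PhantomConfig, group: str = "NM",
                            seed: Optional[int] = None,
                            include_stroma: Optional[bool] = None,
                            median_scale: Optional[dict[str, float]] = None) -> SyntheticPhantom:
    """Render one ground-truthed tissue section for a patient group.

    Per-region concentration fields are lognormal with the configured
    median/quartiles (optionally rescaled per element by ``median_scale``,
    the hook used by :func:`generate_cohort` for between-patient spread);
    Sr and Ba epithelial and adipose fields share a Gaussian copula with the
    configured rank correlation; the forward model applies instrument
    sensitivity, Poisson counting noise, glass background and salt spikes.
    """
    if group not in ("H", "NM", "M"):
        raise ValueError("group must be 'H', 'NM' or 'M'")
    if seed is None:
        seed = config.seed
    if include_stroma is None:
        include_stroma = group != "H"
    rng = np.random.default_rng(seed)
    labels = _build_labels(config, group, include_stroma, rng)
    annotation = RegionAnnotation(labels=labels, legend=dict(DEFAULT_LEGEND))
    adipose = labels == 1
    epithelium = np.isin(labels, (2, 3, 4))
    background = labels == 0
    scale = median_scale or {}

    # rank correlation -> Pearson correlation of the Gaussian copula scores
    # (the sine relation, exact for the bivariate normal copula)
    rho_s = config.sr_ba_rank_correlation
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)

    # copula normal-score fields, shared by Sr and Ba
    sm = config.field_smooth_sigma
    z_sr = _unit_normal_field(rng, config.shape, sm)
    z_ba = r * z_sr + np.sqrt(max(0.0, 1.0 - r**2)) * \
        _unit_normal_field(rng, config.shape, sm)
    z_fields = {"88Sr": z_sr, "138Ba": z_ba}

    truth: dict[str, np.ndarray] = {}
    for el in config.elements:
        field_ = np.zeros(config.shape)
        s = scale.get(el, 1.0)
        z = z_fields.get(el)
        if z is None:
            z = _unit_normal_field(rng, config.shape, sm)
        targets: list[tuple[np.ndarray, float]] = [(adipose, 1.0)]
        has_stroma_split = bool((labels == 4).any())
        if has_stroma_split:
            ratio = config.niche_stroma_ratio.get(el, 1.0)
            targets += [(labels == 3, np.sqrt(ratio)),
                        (labels == 4, 1.0 / np.sqrt(ratio))]
        else:
            targets.append((epithelium, 1.0))
        for region_mask, factor in targets:
            spec = (config.adipose_conc[el] if region_mask is adipose
                    else config.conc[el][group])
            m, q1, q3 = spec
            mu, sigma = lognormal_params(m * s * factor, q1 * s * factor,
                                         q3 * s * factor)
            field_[region_mask] = np.exp(mu + sigma * z[region_mask])
        truth[el] = field_

    geo = config.geometry
    if group in geo.hotspot_groups and geo.hotspot_element in truth:
        epi_idx = np.argwhere(epithelium)
        for _ in range(geo.hotspot_count):
            center = epi_idx[rng.integers(len(epi_idx))]
            spot = _disc(config.shape, tuple(center), geo.hotspot_radius) & epithelium
            truth[geo.hotspot_element][spot] *= geo.hotspot_amplitude

    # forward model
    noise = config.noise
    dwell_s = config.meta.dwell_ms / 1000.0
    images: dict[str, ElementImage] = {}
    for el in config.elements:
        slope, intercept = config.sensitivity[el]
        expected = slope * truth[el] + intercept
        if noise.poisson:
            intensity = rng.poisson(expected * dwell_s).astype(float) / dwell_s
            glass = np.maximum(
                0.0, rng.normal(noise.glass_level, noise.glass_sd,
                                size=config.shape))
        else:
            intensity = expected.copy()
            glass = np.full(config.shape, noise.glass_level)
        intensity[background] = glass[background]
        if noise.poisson and noise.spike_prob > 0:
            spikes = rng.random(config.shape) < noise.spike_prob
            intensity[spikes] *= noise.spike_factor
        images[el] = ElementImage(el, intensity, config.meta)

    stack = ImageStack(images=images, sample_id=f"phantom_{group}_{seed}")
    return SyntheticPhantom(stack=stack, truth_conc=truth,
                            annotation=annotation, config=config)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(config: PhantomConfig, n_h: int = 4, n_nm: int = 7,
                    n_m: int = 11, seed: Optional[int] = None,
                    stroma_retained: dict[str, int] | None = None
                    ) -> list[tuple[SyntheticPhantom, SampleRecord]]:
    """Generate an H/NM/M cohort of phantoms with patient-level variability.

    Each sample draws a per-element lognormal median multiplier
    (sigma = ``config.between_sample_sigma``) applied to all its regions, so
    per-sample medians vary between patients as in a real cohort.  By
    default 5 NM and 8 M samples retain a stroma compartment (widespread
    cancers lack one).  Fully deterministic for a fixed seed.
    """
    if seed is None:
        seed = config.seed
    if stroma_retained is None:
        stroma_retained = {"NM": 5, "M": 8}
    rng = np.random.default_rng(seed)
    out: list[tuple[SyntheticPhantom, SampleRecord]] = []
    for group, n in (("H", n_h), ("NM", n_nm), ("M", n_m)):
        n_stroma = min(stroma_retained.get(group, n), n)
        with_stroma = np.zeros(n, dtype=bool)
        if group != "H" and n > 0:
            with_stroma[rng.choice(n, size=n_stroma, replace=False)] = True
        for i in range(n):
            sample_seed = int(rng.integers(2**31))
            scale = {el: float(np.exp(config.between_sample_sigma *
                                      rng.standard_normal()))
                     for el in config.elements}
            if group == "H":
                er = pr = her2 = None
            else:
                er = int(rng.random() < 0.7)
                pr = int(rng.random() < 0.6)
                her2 = int(rng.random() < 0.3)
            phantom = generate_tissue_phantom(
                config, group, seed=sample_seed,
                include_stroma=bool(with_stroma[i]) if group != "H" else False,
                median_scale=scale)
            sample_id = f"{group}{i + 1:02d}"
            phantom.stack.sample_id = sample_id
            record = SampleRecord(sample_id=sample_id, group=group,
                                  er=er, pr=pr, her2=her2)
            out.append((phantom, record))
    return out


def sample_cohort_medians(config: PhantomConfig,
                          group_sizes: dict[str, int] | None = None,
                          seed: int = 0, n_pixels: int = 5000,
                          regions: tuple[str, ...] = ("epithelial",)) -> pd.DataFrame:
    """Fast statistical path: draw per-sample region medians directly.

    Reproduces the cohort's two-level model (between-sample multiplier x
    within-sample median-estimation noise) without rendering images; used
    for level/power simulations where only the medians matter.  The
    within-sample sampling error of a lognormal median over ``n_pixels``
    pixels is ~ exp(1.2533 sigma / sqrt(n)) applied multiplicatively.
    """
    if group_sizes is None:
        group_sizes = {"H": 4, "NM": 7, "M": 11}
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in group_sizes.items():
        for i in range(n):
            mult = {el: np.exp(config.between_sample_sigma * rng.standard_normal())
                    for el in config.elements}
            for el in config.elements:
                for region in regions:
                    spec = (config.adipose_conc[el] if region == "adipose"
                            else config.conc[el][group])
                    mu, sigma = lognormal_params(*spec)
                    se = 1.2533 * sigma / np.sqrt(n_pixels)
                    med = np.exp(mu + np.log(mult[el]) + se * rng.standard_normal())
                    rows.append({"sample_id": f"{group}{i + 1:02d}",
                                 "group": group, "element": el,
                                 "region": region, "median": med})
    return pd.DataFrame(rows)
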