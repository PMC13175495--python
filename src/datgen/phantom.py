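"""Synthetic dual-phase [18F]-FP-CIT brain phantom.

Builds a voxelized head with an occipital reference region and the six
striatal subregions used in DAT quantification (caudate CA, anterior/posterior
putamen AP/PP, ventral striatum VS, per hemisphere), paints region
time-activity curves into it at the five early-frame times (31..39 min
post-injection) and the delayed time (180 min), then applies system-resolution
blur and additive noise.

Kinetic model
-------------
Occipital (reference) and cortex follow a mono-exponentially clearing
perfusion curve; striatal regions add a saturating specific-binding component:

    occipital(t) = A exp(-t/tau) + B
    striatum(t)  = perf_ratio * occipital(t) + S (1 - exp(-t/tau_s)) * f

where ``f`` is the regional binding-reduction factor.  Degenerative
parkinsonism (DP) reduces ``f`` with a ventrodorsal / rostrocaudal gradient
(posterior putamen most affected), optionally asymmetrically; the non-DP
pattern instead applies patchy per-region lesions without that gradient.
With the default parameters a normal subject has delayed putaminal SUVR
around 7.7 and early-phase (35 min) striatal SUVR around 2, rising contrast
over time, while severity information is already present (attenuated) in the
early frames — the structure the translation model must learn.

Axis convention: arrays are (z, y, x) with z index 0 the most superior slice,
y increasing posteriorly, x increasing to the subject's right.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Region label codes.
BACKGROUND, CORTEX, OCCIPITAL = 0, 1, 2
STRIATAL_REGIONS = ("CA", "AP", "PP", "VS")
HEMISPHERES = ("L", "R")
#: label code for (region, hemisphere): left 10..13, right 20..23
REGION_CODES = {
    (r, h): (10 if h == "L" else 20) + i
    for i, r in enumerate(STRIATAL_REGIONS)
    for h in HEMISPHERES
}

EARLY_FRAME_TIMES_MIN = (31.0, 33.0, 35.0, 37.0, 39.0)
DELAYED_TIME_MIN = 180.0

SUBJECT_CLASSES = ("normal", "DP", "nonDP")

#: severity-gradient weights: reduction factor = 1 - severity * weight.
#: PP most affected, VS least (ventrodorsal / rostrocaudal gradient of DP).
DP_GRADIENT = {"PP": 0.90, "AP": 0.70, "CA": 0.35, "VS": 0.20}


@dataclass(frozen=True)
class TacModel:
    """Per-region SUV(t) parameters (SUV units, minutes)."""

    occ_amplitude: float = 3.0
    occ_tau: float = 60.0
    occ_baseline: float = 0.5
    cortex_ratio: float = 0.95     # cortex = ratio * occipital curve
    striatum_perf_ratio: float = 1.1
    binding_plateau: float = 4.5   # S for CA/AP/PP
    binding_plateau_vs: float = 3.8
    binding_tau: float = 60.0

    def occipital(self, t: float) -> float:
        return self.occ_amplitude * np.exp(-t / self.occ_tau) + self.occ_baseline

    def striatal(self, region: str, t: float, reduction: float = 1.0) -> float:
        s = self.binding_plateau_vs if region == "VS" else self.binding_plateau
        perf = self.striatum_perf_ratio * self.occipital(t)
        return perf + s * (1.0 - np.exp(-t / self.binding_tau)) * reduction


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 64, 64)  # (z, y, x)
    voxel_mm: float = 2.0
    subject_class: str = "normal"
    severity: float = 0.0
    asymmetry: float = 0.0
    noise_sd: float = 0.1
    blur_fwhm_mm: float = 6.0
    seed: int = 0
    tac: TacModel = field(default_factory=TacModel)

    def __post_init__(self):
        if self.subject_class not in SUBJECT_CLASSES:
            raise ValueError(f"unknown subject_class {self.subject_class!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if min(self.grid_shape) < 32:
            raise ValueError("grid_shape must be >= 32 voxels per axis")


@dataclass
class RegionAtlas:
    """Integer label volume; codes per REGION_CODES plus cortex/occipital."""

    labels: np.ndarray
    voxel_mm: float

    def mask(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        """Boolean mask for a region; composite regions P and WS supported."""
        if region == "occipital":
            return self.labels == OCCIPITAL
        if region == "cortex":
            return self.labels == CORTEX
        if region == "P":
            return self.mask("AP", hemisphere) | self.mask("PP", hemisphere)
        if region == "WS":
            m = np.zeros(self.labels.shape, dtype=bool)
            for r in STRIATAL_REGIONS:
                m |= self.mask(r, hemisphere)
            return m
        if region not in STRIATAL_REGIONS:
            raise KeyError(f"unknown region {region!r}")
        hemis = HEMISPHERES if hemisphere is None else (hemisphere,)
        m = np.zeros(self.labels.shape, dtype=bool)
        for h in hemis:
            m |= self.labels == REGION_CODES[(region, h)]
        return m


@dataclass
class StudyMeta:
    subject_class: str
    severity: float
    asymmetry: float
    seed: int
    #: ground-truth binding-reduction factor per (region, hemisphere)
    reduction: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DualPhaseStudy:
    early_frames: list[np.ndarray]   # five 3D SUV volumes, time-ordered
    delayed: np.ndarray              # 3D SUV volume at 180 min
    atlas: RegionAtlas
    meta: StudyMeta


# ----------------------------------------------------------------------------
# Atlas geometry (voxel units on the default 2 mm grid; scaled by voxel_mm).
# Left-hemisphere ellipsoids; the right hemisphere is the exact mirror about
# the midsagittal plane, so hemisphere voxel counts match by construction.
# ----------------------------------------------------------------------------

_BRAIN = dict(center=(23.0, 31.5, 31.5), radii=(21.0, 29.0, 27.0))       # (z,y,x)
_OCC = dict(center=(25.0, 53.0, 31.5), radii=(9.0, 7.5, 13.0))
_LEFT_ELLIPSOIDS = {
    "CA": dict(center=(20.0, 24.0, 22.0), radii=(4.0, 5.0, 3.5)),
    "AP": dict(center=(23.0, 29.0, 25.5), radii=(4.0, 3.5, 3.5)),
    "PP": dict(center=(23.0, 37.0, 26.5), radii=(4.0, 3.5, 3.5)),
    "VS": dict(center=(28.5, 25.0, 23.0), radii=(3.0, 3.0, 3.0)),
}


def _ellipsoid_mask(shape, center, radii, scale: float = 1.0) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                             indexing="ij")
    cz, cy, cx = (c * scale for c in center)
    rz, ry, rx = (max(r * scale, 1.0) for r in radii)
    d = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return d <= 1.0


def build_atlas(spec: PhantomSpec) -> RegionAtlas:
    """Construct the region atlas for a phantom grid.

    Striatal subregions are painted with precedence CA > AP > PP > VS so the
    codes are disjoint even where ellipsoids touch; the right hemisphere is
    the mirror image of the left.
    """
    shape = spec.grid_shape
    scale = 2.0 / spec.voxel_mm  # geometry is defined on the 2 mm grid
    sz, sy, sx = shape

    def chk(name, geo):
        cz, cy, cx = geo["center"]
        rz, ry, rx = geo["radii"]
        if (cz + rz) * scale >= sz or (cy + ry) * scale >= sy or (cx + rx) * scale >= sx \
                or (cz - rz) * scale < 0 or (cy - ry) * scale < 0 or (cx - rx) * scale < 0:
            raise ValueError(f"grid {shape} too small to contain region {name}")

    chk("brain", _BRAIN)
    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid_mask(shape, _BRAIN["center"], _BRAIN["radii"], scale)] = CORTEX
    occ = _ellipsoid_mask(shape, _OCC["center"], _OCC["radii"], scale)
    chk("occipital", _OCC)
    labels[occ & (labels == CORTEX)] = OCCIPITAL

    for region in STRIATAL_REGIONS:  # precedence order
        geo = _LEFT_ELLIPSOIDS[region]
        chk(region, geo)
        left = _ellipsoid_mask(shape, geo["center"], geo["radii"], scale)
        right = left[:, :, ::-1]
        for h, m in (("L", left), ("R", right)):
            sel = m & ((labels == CORTEX) | (labels == BACKGROUND))
            if not sel.any():
                raise ValueError(f"region {region}/{h} empty on grid {shape}")
            labels[sel] = REGION_CODES[(region, h)]

    atlas = RegionAtlas(labels=labels, voxel_mm=spec.voxel_mm)
    if not (atlas.labels == OCCIPITAL).any():
        raise ValueError("occipital region empty")
    return atlas


# ----------------------------------------------------------------------------
# Time-activity curves
# ----------------------------------------------------------------------------

def reduction_factor(region: str, subject_class: str, severity: float,
                     hemisphere: str = "L", asymmetry: float = 0.0) -> float:
    """Ground-truth multiplicative binding factor for a striatal subregion.

    DP applies the ventrodorsal gradient; normal (and the deterministic part
    of nonDP) leaves binding intact.  Asymmetry shifts severity by +a/2 on the
    left and -a/2 on the right hemisphere, clipped to [0, 1].
    """
    if region not in STRIATAL_REGIONS:
        raise KeyError(f"unknown striatal region {region!r}")
    if subject_class != "DP" or severity == 0.0:
        return 1.0
    s = severity + (0.5 if hemisphere == "L" else -0.5) * asymmetry
    s = float(np.clip(s, 0.0, 1.0))
    return 1.0 - s * DP_GRADIENT[region]


def tac_suv(region, t: float, subject_class: str = "normal",
            severity: float = 0.0, hemisphere: str = "L",
            asymmetry: float = 0.0, tac: TacModel | None = None) -> float:
    """SUV of a region at time t (minutes post-injection).

    ``region`` is one of the striatal codes, "occipital" or "cortex".  The
    occipital and cortex curves are independent of subject class and severity.
    """
    if t <= 0:
        raise ValueError("t must be positive (minutes post-injection)")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    tac = tac or TacModel()
    if region == "occipital":
        return float(tac.occipital(t))
    if region == "cortex":
        return float(tac.cortex_ratio * tac.occipital(t))
    f = reduction_factor(region, subject_class, severity, hemisphere, asymmetry)
    return float(tac.striatal(region, t, f))


# ----------------------------------------------------------------------------
# Study simulation
# ----------------------------------------------------------------------------

def _nondp_lesions(rng: np.random.Generator) -> dict[str, float]:
    """Patchy focal defects: 1-3 random (region, hemisphere) sites with a
    uniform reduction, deliberately without the DP gradient ordering."""
    factors = {f"{r}/{h}": 1.0 for r in STRIATAL_REGIONS for h in HEMISPHERES}
    sites = rng.choice(len(factors), size=rng.integers(1, 4), replace=False)
    keys = list(factors)
    for s in sites:
        factors[keys[s]] = float(rng.uniform(0.3, 0.7))
    return factors


def _paint(atlas: RegionAtlas, t: float, tac: TacModel,
           factors: dict[str, float]) -> np.ndarray:
    vol = np.zeros(atlas.labels.shape, dtype=np.float64)
    vol[atlas.labels == CORTEX] = tac.cortex_ratio * tac.occipital(t)
    vol[atlas.labels == OCCIPITAL] = tac.occipital(t)
    for r in STRIATAL_REGIONS:
        for h in HEMISPHERES:
            vol[atlas.labels == REGION_CODES[(r, h)]] = tac.striatal(
                r, t, factors[f"{r}/{h}"])
    return vol


def simulate_study(spec: PhantomSpec) -> DualPhaseStudy:
    """Simulate one subject: five early frames plus the delayed volume.

    Fully determined by ``spec`` (including its seed): blur and noise are
    applied identically at every time point with an independent noise draw
    per frame.
    """
    atlas = build_atlas(spec)
    rng = np.random.default_rng(spec.seed)

    if spec.subject_class == "nonDP":
        factors = _nondp_lesions(rng)
    else:
        factors = {
            f"{r}/{h}": reduction_factor(r, spec.subject_class, spec.severity,
                                         h, spec.asymmetry)
            for r in STRIATAL_REGIONS for h in HEMISPHERES
        }

    sigma = spec.blur_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_mm

    def render(t: float) -> np.ndarray:
        vol = _paint(atlas, t, spec.tac, factors)
        if sigma > 0:
            vol = gaussian_filter(vol, sigma, mode="constant")
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)
        return np.maximum(vol, 0.0).astype(np.float32)

    early = [render(t) for t in EARLY_FRAME_TIMES_MIN]
    delayed = render(DELAYED_TIME_MIN)
    meta = StudyMeta(subject_class=spec.subject_class, severity=spec.severity,
                     asymmetry=spec.asymmetry, seed=spec.seed,
                     reduction=factors)
    return DualPhaseStudy(early_frames=early, delayed=delayed, atlas=atlas,
                          meta=meta)


#: per-class severity ranges the cohort simulator draws from
SEVERITY_RANGES = {"normal": (0.0, 0.0), "DP": (0.4, 0.9), "nonDP": (0.0, 0.0)}
ASYMMETRY_RANGE = (0.0, 0.3)


def simulate_cohort(n_normal: int, n_dp: int, n_nondp: int, base_seed: int = 0,
                    **spec_overrides) -> list[DualPhaseStudy]:
    """Simulate a cohort with deterministic per-subject seeds.

    Severities are drawn per subject from SEVERITY_RANGES (DP uniform on
    [0.4, 0.9], mild asymmetry); nonDP subjects carry patchy lesions drawn
    inside simulate_study.  ``spec_overrides`` apply to every subject (e.g.
    noise_sd=0).
    """
    if min(n_normal, n_dp, n_nondp) < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_normal + n_dp + n_nondp == 0:
        raise ValueError("cohort is empty: all counts are zero")
    master = np.random.default_rng(np.random.SeedSequence(base_seed))
    studies = []
    for cls, n in (("normal", n_normal), ("DP", n_dp), ("nonDP", n_nondp)):
        lo, hi = SEVERITY_RANGES[cls]
        for _ in range(n):
            sev = float(master.uniform(lo, hi)) if hi > lo else lo
            asym = float(master.uniform(*ASYMMETRY_RANGE)) if cls == "DP" else 0.0
            seed = int(master.integers(0, 2**31 - 1))
            spec = PhantomSpec(subject_class=cls, severity=sev, asymmetry=asym,
                               seed=seed, **spec_overrides)
            studies.append(simulate_study(spec))
    return studies
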