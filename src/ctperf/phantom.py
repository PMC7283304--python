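"""Digital CT-perfusion phantom with known regional perfusion truth.

A subject is a 4D spatio-temporal attenuation volume built from the
indicator-dilution model: each voxel's time-attenuation curve is the
convolution of a gamma-variate arterial input function (AIF) with a
mono-exponential residue function, scaled by the regional cerebral blood
flow and shifted by a regional bolus-arrival delay.  Three tissue
compartments (normal, penumbra, core) follow the perfusion ordering
``core CBF < penumbra CBF < normal CBF`` with prolonged transit times and
delays in the lesion.  The ground-truth final-infarct mask is
``core ∪ penumbra`` for subjects without successful recanalization
(group A) and ``core`` alone for successfully recanalized subjects
(group B).

All quantities use the field's conventional units: CBF in ml/100 g/min,
CBV in ml/100 g, MTT and delay in seconds; the central volume principle
``CBV = CBF · MTT / 60`` holds exactly in the truth maps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AIFSpec", "RegionSpec", "PhantomSpec", "CTPStudy", "SubjectTruth",
    "CohortSampler", "evaluate_aif", "simulate_tissue_curve",
    "build_subject", "build_cohort", "DEFAULT_NOISE_SD",
]

Group = Literal["A", "B"]

#: Default additive-noise standard deviation (attenuation/concentration
#: units).  Calibrated once against the default AIF and region parameters so
#: that the peak contrast between normal and core tissue curves is ~5 times
#: the noise floor (a 5:1 lesion/normal contrast-to-noise ratio).
DEFAULT_NOISE_SD = 0.24

REGION_CODES = {"normal": 0, "penumbra": 1, "core": 2}


class InvalidSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class AIFSpec:
    """Gamma-variate arterial input function.

    AIF(t) = amplitude * (t - t0)^alpha * exp(-(t - t0) / beta) for t > t0,
    zero before bolus arrival.  The peak sits at ``t0 + alpha * beta``.
    """

    amplitude: float = 10.0   # concentration units
    t0: float = 8.0           # bolus arrival, s
    alpha: float = 3.0        # shape, dimensionless
    beta: float = 1.5         # time scale, s

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.beta <= 0:
            raise InvalidSpecError(
                "AIF amplitude and beta must be positive, got "
                f"amplitude={self.amplitude}, beta={self.beta}"
            )
        if self.alpha <= 0 or self.t0 < 0:
            raise InvalidSpecError("AIF requires alpha > 0 and t0 >= 0")


@dataclass(frozen=True)
class RegionSpec:
    """One tissue compartment with its true perfusion parameters.

    ``geometry`` is an ellipsoid (center, radii) in voxel coordinates for
    lesion compartments; the normal compartment is the background and has
    no geometry.  CBV is never stored: it is derived from the central
    volume principle, ``cbv_true = cbf_true * mtt_true / 60``.
    """

    label: Literal["normal", "penumbra", "core"]
    cbf_true: float           # ml/100 g/min
    mtt_true: float           # s
    delay_true: float = 0.0   # bolus-arrival delay vs the AIF, s
    center: tuple[float, float, float] | None = None  # voxel coords
    radii: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.cbf_true < 0 or self.mtt_true <= 0 or self.delay_true < 0:
            raise InvalidSpecError(
                f"region {self.label!r}: needs cbf >= 0, mtt > 0, delay >= 0"
            )
        if self.label != "normal" and (self.center is None or self.radii is None):
            raise InvalidSpecError(f"lesion region {self.label!r} needs geometry")

    @property
    def cbv_true(self) -> float:
        """ml/100 g, by the central volume principle."""
        return self.cbf_true * self.mtt_true / 60.0


def _default_regions() -> tuple[RegionSpec, ...]:
    # Ordering core < penumbra < normal in CBF, reversed in MTT/delay,
    # consistent with the lesion-direction conventions of the threshold
    # grids.  Values are simulator defaults, not measured cohort values.
    return (
        RegionSpec("normal", cbf_true=60.0, mtt_true=4.0, delay_true=0.0),
        RegionSpec("penumbra", cbf_true=25.0, mtt_true=7.0, delay_true=3.0,
                   center=(23.0, 16.0, 4.0), radii=(6.0, 7.0, 3.0)),
        RegionSpec("core", cbf_true=8.0, mtt_true=10.0, delay_true=6.0,
                   center=(23.0, 16.0, 4.0), radii=(3.0, 4.0, 2.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic CTP subject.

    The grid is left-right symmetric about the midline sagittal plane
    x = (nx - 1) / 2 with nx even, so the contralateral mirror is the exact
    index flip ``x -> nx - 1 - x``.  Lesion ellipsoids must stay inside the
    x > midline hemisphere.  ``coverage_fraction < 1`` crops the coverage
    mask to a central craniocaudal slab, emulating scanners with a reduced
    field of view.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 5.0)  # mm
    n_timepoints: int = 30
    dt: float = 2.0           # s; 30 x 2 s = 60 s scan
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    aif: AIFSpec = field(default_factory=AIFSpec)
    noise_sd: float = DEFAULT_NOISE_SD
    coverage_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx = self.grid_shape[0]
        if nx % 2 != 0:
            raise InvalidSpecError("grid x-dimension must be even (exact mirror)")
        if self.dt <= 0 or self.n_timepoints < 2:
            raise InvalidSpecError("need dt > 0 and at least 2 timepoints")
        if not 0 < self.coverage_fraction <= 1:
            raise InvalidSpecError("coverage_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        labels = [r.label for r in self.regions]
        if "normal" not in labels:
            raise InvalidSpecError("a 'normal' background region is required")
        midline = (nx - 1) / 2.0
        for r in self.regions:
            if r.label == "normal":
                continue
            cx, rx = r.center[0], r.radii[0]
            if cx - rx <= midline:
                raise InvalidSpecError(
                    f"lesion {r.label!r} crosses the midline (x extent "
                    f"{cx - rx:.1f} <= {midline}); the contralateral "
                    "reference would be corrupted"
                )
            for c, rad, n in zip(r.center, r.radii, self.grid_shape):
                if c - rad < -0.5 or c + rad > n - 0.5:
                    raise InvalidSpecError(f"lesion {r.label!r} exceeds the grid")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt

    def region(self, label: str) -> RegionSpec:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class CTPStudy:
    """One subject's 4D CTP acquisition (x, y, z, t) plus geometry."""

    data: np.ndarray                       # (nx, ny, nz, nt), concentration
    dt: float                              # s
    voxel_size: tuple[float, float, float]  # mm
    coverage_mask: np.ndarray              # (nx, ny, nz) bool
    subject_id: str
    group: Group

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise InvalidSpecError(f"group must be 'A' or 'B', got {self.group!r}")
        if self.data.shape[:3] != self.coverage_mask.shape:
            raise InvalidSpecError("coverage_mask shape must match spatial grid")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSpecError("study data must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[3]) * self.dt

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass
class SubjectTruth:
    """Voxel-wise ground truth attached to a synthetic subject."""

    region_label_map: np.ndarray   # int codes, see REGION_CODES
    fiv_mask_true: np.ndarray      # bool, the reference infarct mask
    cbf_true: np.ndarray
    cbv_true: np.ndarray
    mtt_true: np.ndarray
    delay_true: np.ndarray


def evaluate_aif(spec: AIFSpec, times: np.ndarray) -> np.ndarray:
    """Sample the gamma-variate AIF at the given times.

    Zero before bolus arrival ``t0``; strictly positive after.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    m = times > spec.t0
    tt = times[m] - spec.t0
    out[m] = spec.amplitude * tt ** spec.alpha * np.exp(-tt / spec.beta)
    return out


def simulate_tissue_curve(
    aif: np.ndarray,
    cbf_true: float,
    mtt_true: float,
    delay_true: float,
    dt: float,
) -> np.ndarray:
    """Tissue time-attenuation curve from the indicator-dilution model.

    C(t) = (CBF / (100 * 60)) * [AIF ⊛ R](t - delay) with the
    mono-exponential residue R(t) = exp(-t / MTT), discretised as a
    Riemann sum with step ``dt``.  The delay is rounded to the nearest
    sample (half up), so a delayed curve is an exact shift of the
    undelayed one.
    """
    if dt <= 0:
        raise InvalidSpecError("dt must be positive")
    if mtt_true <= 0:
        raise InvalidSpecError("mtt_true must be positive")
    if cbf_true < 0 or delay_true < 0:
        raise InvalidSpecError("cbf_true and delay_true must be non-negative")
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    t = np.arange(n) * dt
    residue = np.exp(-t / mtt_true)
    flow = cbf_true / 6000.0  # ml/g/s
    curve = flow * dt * np.convolve(aif, residue)[:n]
    shift = int(np.floor(delay_true / dt + 0.5))
    if shift > 0:
        curve = np.concatenate([np.zeros(shift), curve[: n - shift]])
    return curve


def _region_label_map(spec: PhantomSpec) -> np.ndarray:
    """Assign every voxel to exactly one region; core overrides penumbra."""
    nx, ny, nz = spec.grid_shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    for name in ("penumbra", "core"):  # core painted last, wins
        try:
            r = spec.region(name)
        except KeyError:
            continue
        cx, cy, cz = r.center
        rx, ry, rz = r.radii
        inside = (
            ((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2
        ) <= 1.0
        labels[inside] = REGION_CODES[name]
    return labels


def build_subject(
    spec: PhantomSpec,
    group: Group,
    seed: int | None = None,
    subject_id: str | None = None,
) -> tuple[CTPStudy, SubjectTruth]:
    """Simulate one subject: region curves + i.i.d. Gaussian noise.

    The ground-truth infarct mask is core ∪ penumbra for group A (no or
    failed recanalization: the whole hypoperfused territory infarcts) and
    core alone for group B (successful recanalization salvages the
    penumbra).  Identical spec and seed give bit-identical output.
    """
    if seed is None:
        seed = spec.seed
    labels = _region_label_map(spec)
    aif = evaluate_aif(spec.aif, spec.times)

    nt = spec.n_timepoints
    data = np.zeros(spec.grid_shape + (nt,), dtype=float)
    truth_maps = {k: np.zeros(spec.grid_shape) for k in ("cbf", "cbv", "mtt", "delay")}
    for r in spec.regions:
        mask = labels == REGION_CODES[r.label]
        if not mask.any():
            continue
        curve = simulate_tissue_curve(aif, r.cbf_true, r.mtt_true, r.delay_true, spec.dt)
        data[mask] = curve
        truth_maps["cbf"][mask] = r.cbf_true
        truth_maps["cbv"][mask] = r.cbv_true
        truth_maps["mtt"][mask] = r.mtt_true
        truth_maps["delay"][mask] = r.delay_true

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    coverage = np.ones(spec.grid_shape, dtype=bool)
    if spec.coverage_fraction < 1.0:
        nz = spec.grid_shape[2]
        keep = max(1, int(round(nz * spec.coverage_fraction)))
        lo = (nz - keep) // 2
        coverage[:, :, :lo] = False
        coverage[:, :, lo + keep:] = False

    if group == "A":
        fiv = labels > 0
    else:
        fiv = labels == REGION_CODES["core"]

    study = CTPStudy(
        data=data,
        dt=spec.dt,
        voxel_size=spec.voxel_size,
        coverage_mask=coverage,
        subject_id=subject_id or f"sub-{seed:03d}",
        group=group,
    )
    truth = SubjectTruth(
        region_label_map=labels,
        fiv_mask_true=fiv,
        cbf_true=truth_maps["cbf"],
        cbv_true=truth_maps["cbv"],
        mtt_true=truth_maps["mtt"],
        delay_true=truth_maps["delay"],
    )
    return study, truth


@dataclass(frozen=True)
class CohortSampler:
    """Per-subject parameter ranges for cohort simulation.

    Each range is inclusive ``(low, high)``; a degenerate range (low ==
    high) pins the parameter.  Lesion size varies through a common scale
    factor applied to the default ellipsoid radii.  ``half_coverage_rate``
    is the fraction of subjects acquired with a half-thickness craniocaudal
    slab (scanners with a reduced field of view).
    """

    normal_cbf: tuple[float, float] = (50.0, 70.0)
    normal_mtt: tuple[float, float] = (3.5, 4.5)
    penumbra_cbf: tuple[float, float] = (18.0, 32.0)
    penumbra_mtt: tuple[float, float] = (5.0, 9.0)
    penumbra_delay: tuple[float, float] = (2.0, 5.0)
    core_cbf: tuple[float, float] = (5.0, 12.0)
    core_mtt: tuple[float, float] = (8.0, 12.0)
    core_delay: tuple[float, float] = (6.0, 10.0)
    lesion_scale: tuple[float, float] = (0.6, 1.15)
    half_coverage_rate: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                if not (len(v) == 2 and v[0] <= v[1]):
                    raise InvalidSpecError(f"empty range for {f.name}: {v}")
        if not 0 <= self.half_coverage_rate <= 1:
            raise InvalidSpecError("half_coverage_rate must be in [0, 1]")


def _sample_spec(
    base: PhantomSpec, sampler: CohortSampler, rng: np.random.Generator
) -> PhantomSpec:
    u = lambda lohi: float(rng.uniform(*lohi)) if lohi[0] < lohi[1] else lohi[0]
    scale = u(sampler.lesion_scale)
    base_pen = base.region("penumbra")
    base_core = base.region("core")
    pen_radii = tuple(r * scale for r in base_pen.radii)
    core_radii = tuple(min(r * scale, p) for r, p in zip(base_core.radii, pen_radii))
    # Pin the lesion center so the scaled ellipsoid stays inside one
    # hemisphere; the spec validator rejects any violation.
    regions = (
        RegionSpec("normal", cbf_true=u(sampler.normal_cbf),
                   mtt_true=u(sampler.normal_mtt), delay_true=0.0),
        RegionSpec("penumbra", cbf_true=u(sampler.penumbra_cbf),
                   mtt_true=u(sampler.penumbra_mtt),
                   delay_true=u(sampler.penumbra_delay),
                   center=base_pen.center, radii=pen_radii),
        RegionSpec("core", cbf_true=u(sampler.core_cbf),
                   mtt_true=u(sampler.core_mtt),
                   delay_true=u(sampler.core_delay),
                   center=base_core.center, radii=core_radii),
    )
    coverage = 0.5 if rng.uniform() < sampler.half_coverage_rate else 1.0
    return replace(base, regions=regions, coverage_fraction=coverage)


def build_cohort(
    n_a: int = 25,
    n_b: int = 29,
    sampler: CohortSampler | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[CTPStudy, SubjectTruth, PhantomSpec]]:
    """Simulate a two-group cohort (defaults: 25 group-A + 29 group-B).

    Per-subject perfusion parameters and lesion size are drawn from the
    sampler's ranges using seeds derived from the global seed, so the
    cohort is reproducible and each subject is independently perturbed.
    """
    if n_a < 1 or n_b < 1:
        raise InvalidSpecError("need at least one subject per group")
    sampler = sampler or CohortSampler()
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_a + n_b)
    out: list[tuple[CTPStudy, SubjectTruth, PhantomSpec]] = []
    groups = ["A"] * n_a + ["B"] * n_b
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        spec = _sample_spec(base, sampler, rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        study, truth = build_subject(
            spec, group, seed=noise_seed, subject_id=f"sub-{i:03d}"
        )
        out.append((study, truth, spec))
    return out
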