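"""Synthetic dynamic brain-PET phantom with known ground truth.

Emulates an HRRT-like acquisition at desk scale: a Feng tri-exponential
arterial bolus feeds two thin carotid tubes in the lowest planes, a wider
venous sinus carries the same bolus delayed and dispersed, and cuboid tissue
regions follow two-tissue-compartment kinetics driven by the true
metabolite-corrected plasma input. Each frame is the time-average of the
analytic curves over the frame interval; the volume is blurred with an
isotropic Gaussian PSF and corrupted with count-scaled noise. Every
downstream extraction and fitting stage can therefore be tested for
parameter recovery against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .blood import BiExpParams, HillParams, apply_dispersion
from .curves import FrameSchedule, InputFunction, TimeActivityCurve
from .image import DynamicImage
from .io import ManualSample
from .kinetics import TCM2Params, tcm2_forward

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_SAMPLE_TIMES_MIN = (1.5, 2.5, 7.0, 15.0, 30.0, 45.0, 60.0, 90.0)


@dataclass(frozen=True)
class FengParams:
    """Feng tri-exponential bolus: the standard simulated arterial input.

    C(t) = (A1 (t-t0) - A2 - A3) e^{-l1 (t-t0)} + A2 e^{-l2 (t-t0)} + A3 e^{-l3 (t-t0)}
    for t >= t0, zero before the appearance time t0. Amplitudes in kBq/mL
    (A1 in kBq/mL/s), rates in 1/s, l1 > l2 > l3 > 0. The form is continuous
    at t0 and decays to zero.
    """

    t0: float = 20.0
    A1: float = 40.0
    A2: float = 8.0
    A3: float = 6.0
    l1: float = 0.2
    l2: float = 0.01
    l3: float = 2.0e-4

    def __post_init__(self):
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("decay constants must be positive")


def bolus_input(t, params: FengParams) -> np.ndarray:
    """Evaluate the Feng bolus at times ``t`` (seconds >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tt = t - params.t0
    val = np.where(
        tt < 0, 0.0,
        (params.A1 * tt - params.A2 - params.A3) * np.exp(-params.l1 * tt)
        + params.A2 * np.exp(-params.l2 * tt)
        + params.A3 * np.exp(-params.l3 * tt))
    return val if val.ndim else float(val)


@dataclass
class Region:
    label: str
    mask: np.ndarray  # boolean volume
    role: str  # "arterial" | "venous" | "tissue"
    params: TCM2Params | None = None  # tissue regions only
    weight: np.ndarray | None = None  # partial-volume fraction, None = 1


def _rasterize_tube(frac: np.ndarray, voxel_size: float, path_fn, radius_fn,
                    z_range, supersample: int = 5) -> None:
    """Accumulate (max) the partial-volume fraction of a tube whose in-plane
    center ``path_fn(z)`` and radius ``radius_fn(z)`` [mm] vary along z,
    by in-plane supersampling."""
    nx, ny, _ = frac.shape
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    for z in range(*z_range):
        cx, cy = path_fn(z)
        r_vox = radius_fn(z) / voxel_size
        half = int(np.ceil(r_vox)) + 1
        for ix in range(max(int(cx) - half, 0), min(int(cx) + half + 1, nx)):
            for iy in range(max(int(cy) - half, 0),
                            min(int(cy) + half + 1, ny)):
                d2 = (ix + ox - cx) ** 2 + (iy + oy - cy) ** 2
                frac[ix, iy, z] = max(frac[ix, iy, z],
                                      float(np.mean(d2 <= r_vox ** 2)))


def _taper(base_mm, amp, wavelength, phase):
    return lambda z: base_mm * (1.0 + amp * np.sin(2 * np.pi * z / wavelength
                                                   + phase))


def _line(center, tilt, z0):
    return lambda z: (center[0] + tilt[0] * (z - z0),
                      center[1] + tilt[1] * (z - z0))


def _helix(center, radius_vox, pitch, phase, z0, drift=(0.0, 0.0)):
    return lambda z: (
        center[0] + drift[0] * (z - z0)
        + radius_vox * np.cos(2 * np.pi * (z - z0) / pitch + phase),
        center[1] + drift[1] * (z - z0)
        + radius_vox * np.sin(2 * np.pi * (z - z0) / pitch + phase))


def default_background_params() -> TCM2Params:
    """Mixed gray/white brain-like background surrounding all structures
    (V_T = 6 mL/cm^3, toward the low end of measured tissue values, so
    late-scan tissue activity exceeds blood as it does in vivo)."""
    return TCM2Params(0.18, 0.08, 0.05, 0.03)


def build_default_regions(grid_shape: tuple[int, int, int],
                          tissue_params: dict[str, TCM2Params] | None = None,
                          vessel_profile: str = "graded",
                          background: TCM2Params | None = "default",
                          anatomy_rng: np.random.Generator | None = None,
                          ) -> list[Region]:
    """Desk-scale brain-like layout with known ground truth.

    Vasculature: two thin carotid trunks (diameter ~2 voxels) in the lowest
    third of planes with adjacent jugular veins; a wide sagittal-sinus column
    in the upper planes with a thin artery winding alongside; and two
    deep-vein bundles each braided with thin arterial branches. Venous
    structures deliberately occupy more voxels than arterial ones, and thin
    arteries run close to the large veins so that resolution blur produces
    voxels genuinely mixing both signals — the situation blind unmixing of a
    blood-pool ROI actually faces. Cuboid tissue blocks carry each kinetic
    parameter set, and the remaining volume is low-uptake background tissue
    (spill-in source; pass ``background=None`` to leave it empty).

    ``vessel_profile="graded"`` rasterizes vessels as sub-voxel tubes with
    varying caliber (partial-volume fractions, no two planes identical) —
    the realistic default. ``"uniform"`` fills axis-aligned voxel boxes with
    the pure curves — the idealized limit used by exactness tests.
    """
    nx, ny, nz = grid_shape
    if tissue_params is None:
        tissue_params = default_tissue_params()
    voxel = 2.0  # mm reference; fractions depend only on radius/voxel ratio

    def box(xs, ys, zs):
        m = np.zeros(grid_shape, dtype=bool)
        m[xs[0]:xs[1], ys[0]:ys[1], zs[0]:zs[1]] = True
        return m

    sx, sy = 0.515 * nx, 0.727 * ny
    z_car = (0, max(nz // 3, 2))
    z_sin = (round(0.63 * nz), round(0.95 * nz))
    z_mid = (round(0.25 * nz), round(0.88 * nz))
    cx_l, cx_r, cy = round(0.38 * nx), round(0.58 * nx), round(0.5 * ny)
    if vessel_profile == "uniform":
        regions = [
            Region("carotid_left", box((cx_l, cx_l + 2), (cy, cy + 2), z_car),
                   "arterial"),
            Region("carotid_right", box((cx_r, cx_r + 2), (cy, cy + 2), z_car),
                   "arterial"),
            Region("sinus", box((round(sx) - 2, round(sx) + 2),
                                (round(sy) - 2, round(sy) + 2), z_sin),
                   "venous"),
        ]
    elif vessel_profile == "graded":
        rng = anatomy_rng

        def jit_r(base):  # per-subject vessel caliber variation
            return base if rng is None else float(
                base * np.exp(rng.normal(0.0, 0.15)))

        def jit_p(x):  # sub-voxel position variation
            return x if rng is None else float(x + rng.uniform(-0.7, 0.7))

        r_car = jit_r(2.0) if rng is not None else 2.2
        w_a = np.zeros(grid_shape)
        w_v = np.zeros(grid_shape)
        # carotid trunks (thin, lowest third) with adjacent jugular veins
        _rasterize_tube(w_a, voxel, _line((jit_p(cx_l + 0.85), jit_p(cy + 0.4)),
                                          (0.08, -0.05), 0),
                        _taper(r_car, 0.3, 22, 0.0), z_car)
        _rasterize_tube(w_a, voxel, _line((jit_p(cx_r + 1.15), jit_p(cy + 0.6)),
                                          (-0.06, 0.07), 0),
                        _taper(jit_r(r_car), 0.3, 19, 2.0), z_car)
        _rasterize_tube(w_v, voxel, _line((cx_l + 2.35, cy + 1.9),
                                          (0.07, -0.04), 0),
                        _taper(jit_r(2.8), 0.35, 24, 3.0), z_car)
        _rasterize_tube(w_v, voxel, _line((cx_r - 0.35, cy + 2.1),
                                          (-0.05, 0.06), 0),
                        _taper(jit_r(2.8), 0.35, 21, 5.0), z_car)
        # sagittal sinus with a thin artery winding alongside
        _rasterize_tube(w_v, voxel, _line((jit_p(sx), jit_p(sy)),
                                          (0.05, 0.04), z_sin[0]),
                        _taper(jit_r(3.6), 0.3, 26, 1.5), z_sin)
        _rasterize_tube(w_a, voxel, _helix((sx, sy), 3.2, 12, 0.0, z_sin[0],
                                           drift=(0.05, 0.04)),
                        _taper(1.3, 0.3, 20, 1.0), z_sin)
        # deep-vein bundles braided with thin arteries
        for (c, drift, z0, ph) in [((0.385 * nx, 0.615 * ny), (0.12, 0.10),
                                    z_mid[0], 0.0),
                                   ((0.604 * nx, 0.636 * ny), (-0.10, 0.06),
                                    z_mid[0], 2.0)]:
            _rasterize_tube(w_v, voxel, _line(c, drift, z0),
                            _taper(2.6, 0.3, 23, ph), (z0, z_mid[1]))
            for phase, pitch in ((ph, 11), (ph + np.pi, 14)):
                _rasterize_tube(w_a, voxel,
                                _helix(c, 2.6, pitch, phase, z0, drift=drift),
                                _taper(1.2, 0.3, 17, phase), (z0, z_mid[1]))
        a_dom = w_a >= w_v
        m_a = (w_a > 0) & a_dom
        m_v = (w_v > 0) & ~a_dom
        regions = [
            Region("arteries", m_a, "arterial", weight=np.where(m_a, w_a, 0)),
            Region("veins", m_v, "venous", weight=np.where(m_v, w_v, 0)),
        ]
    else:
        raise ValueError(f"unknown vessel profile {vessel_profile!r}")
    # tissue blocks in the outer columns, clear of the vessels
    slots = [((0.10, 0.30), (0.10, 0.30)), ((0.70, 0.90), (0.10, 0.30)),
             ((0.10, 0.30), (0.72, 0.92)), ((0.72, 0.92), (0.72, 0.92)),
             ((0.40, 0.60), (0.08, 0.24))]
    z_tis = (round(0.45 * nz), round(0.85 * nz))
    for (label, params), (xs, ys) in zip(tissue_params.items(), slots):
        regions.append(Region(label, box((round(xs[0] * nx), round(xs[1] * nx)),
                                         (round(ys[0] * ny), round(ys[1] * ny)),
                                         z_tis), "tissue", params))
    if background == "default":
        background = default_background_params()
    if background is not None:
        occupied = np.zeros(grid_shape, dtype=bool)
        for r in regions:
            occupied |= r.mask
        regions.append(Region("background", ~occupied, "tissue",
                              params=background))
    return regions


def default_tissue_params() -> dict[str, TCM2Params]:
    """Physiologically plausible 2-TCM rate sets for five brain regions."""
    return {
        "frontal": TCM2Params(0.25, 0.08, 0.06, 0.025),
        "temporal": TCM2Params(0.22, 0.09, 0.05, 0.03),
        "striatum": TCM2Params(0.28, 0.10, 0.07, 0.03),
        "thalamus": TCM2Params(0.30, 0.09, 0.08, 0.025),
        "cerebellum": TCM2Params(0.20, 0.08, 0.04, 0.03),
    }


def default_b2p() -> BiExpParams:
    return BiExpParams(a1=-0.25, a2=-0.15, b1=0.15, b2=0.02, offset=1.2)


def default_hill() -> HillParams:
    return HillParams(amplitude=0.9, half_time=20.0, slope=2.0)


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic subject reproducibly."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 2.0  # mm
    schedule: FrameSchedule = field(default_factory=FrameSchedule.hrrt_osem)
    arterial_params: FengParams = field(default_factory=FengParams)
    venous_delay: float = 3.0  # s
    venous_dispersion_tau: float = 5.0  # s
    psf_fwhm: float = 2.5  # mm
    noise_scale: float = 5.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0
    vessel_profile: str = "graded"  # or "uniform"
    regions: list[Region] | None = None
    b2p: BiExpParams = field(default_factory=default_b2p)
    hill: HillParams = field(default_factory=default_hill)
    fine_dt: float = 0.1  # s, ground-truth sampling grid

    def __post_init__(self):
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.venous_dispersion_tau < 0 or self.venous_delay < 0:
            raise ValueError("venous delay/dispersion must be >= 0")

    def build_regions(self) -> list[Region]:
        regions = (self.regions if self.regions is not None
                   else build_default_regions(
                       self.grid_shape, vessel_profile=self.vessel_profile))
        if not regions:
            raise ValueError("phantom needs at least one region")
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for r in regions:
            if (occupied & r.mask).any():
                raise ValueError(f"region {r.label} overlaps another region")
            occupied |= r.mask
        return regions


@dataclass
class PhantomTruth:
    """Ground truth paired with one generated phantom image."""

    schedule: FrameSchedule
    fine_times: np.ndarray
    arterial_fine: np.ndarray
    venous_fine: np.ndarray
    parent_plasma_fine: np.ndarray
    arterial: TimeActivityCurve  # frame-averaged
    venous: TimeActivityCurve
    input_function: InputFunction
    region_params: dict[str, TCM2Params]
    region_masks: dict[str, np.ndarray]
    region_roles: dict[str, str]
    b2p: BiExpParams
    hill: HillParams

    @property
    def arterial_curve(self) -> TimeActivityCurve:
        """Continuous (fine-grid) arterial whole-blood curve."""
        return TimeActivityCurve(self.fine_times, self.arterial_fine)

    def manual_samples(self, times_min=DEFAULT_SAMPLE_TIMES_MIN
                       ) -> list[ManualSample]:
        """Bedside samples drawn exactly from the ground truth curves."""
        out = []
        for tm in times_min:
            wb = float(np.interp(tm * 60.0, self.fine_times, self.arterial_fine))
            ratio = float(self.b2p.predict(tm))
            pf = float(self.hill.predict(tm))
            out.append(ManualSample(tm, wb, wb / ratio, pf))
        return out

    def vt_table(self) -> dict[str, float]:
        return {label: p.vt for label, p in self.region_params.items()}


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicImage, PhantomTruth]:
    """Generate one synthetic dynamic PET volume plus its ground truth.

    Vascular voxels carry the arterial or delayed/dispersed venous curve,
    tissue voxels carry analytic 2-TCM curves, all frame-averaged; the volume
    is then PSF-blurred per frame and corrupted with zero-mean noise whose
    variance scales with (local mean / frame duration) * noise_scale^2.
    """
    if spec.psf_fwhm > min(spec.grid_shape) * spec.voxel_size / 2:
        raise ValueError("PSF wider than half the grid extent")
    regions = spec.build_regions()
    sched = spec.schedule
    tgrid = np.arange(0.0, sched.total_time + spec.fine_dt / 2, spec.fine_dt)

    arterial_fine = bolus_input(tgrid, spec.arterial_params)
    art_tac = TimeActivityCurve(tgrid, arterial_fine)
    delayed = np.interp(tgrid - spec.venous_delay, tgrid, arterial_fine,
                        left=0.0)
    venous_fine = apply_dispersion(TimeActivityCurve(tgrid, delayed),
                                   spec.venous_dispersion_tau).values
    t_min = tgrid / 60.0
    parent_fine = (arterial_fine / spec.b2p.predict(t_min)
                   * spec.hill.predict(t_min))
    input_fn = InputFunction(tgrid, parent_fine, provenance="ABSS")

    art_frames = sched.frame_average(tgrid, arterial_fine)
    ven_frames = sched.frame_average(tgrid, venous_fine)

    curves = {}
    region_params, region_masks, region_roles = {}, {}, {}
    for r in regions:
        if r.role == "arterial":
            curves[r.label] = art_frames
        elif r.role == "venous":
            curves[r.label] = ven_frames
        elif r.role == "tissue":
            if r.params is None:
                raise ValueError(f"tissue region {r.label} lacks kinetic params")
            curves[r.label] = tcm2_forward(r.params, input_fn, art_tac,
                                           sched, dt_s=1.0).values
            region_params[r.label] = r.params
        else:
            raise ValueError(f"unknown region role {r.role!r}")
        region_masks[r.label] = r.mask
        region_roles[r.label] = r.role

    vox = np.zeros(spec.grid_shape + (sched.n_frames,))
    for r in regions:
        if r.weight is None:
            vox[r.mask, :] = curves[r.label]
        else:
            vox[r.mask, :] = r.weight[r.mask][:, None] * curves[r.label]

    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * FWHM_TO_SIGMA / spec.voxel_size
        for f in range(sched.n_frames):
            vox[..., f] = gaussian_filter(vox[..., f], sigma_vox,
                                          mode="constant")

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        dur = sched.durations
        if spec.noise_model == "gaussian":
            sd = spec.noise_scale * np.sqrt(np.maximum(vox, 0.0) / dur)
            vox = vox + rng.normal(0.0, 1.0, vox.shape) * sd
        elif spec.noise_model == "poisson":
            lam = np.maximum(vox, 0.0) * dur / spec.noise_scale ** 2
            vox = rng.poisson(lam) * spec.noise_scale ** 2 / dur
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
        vox = np.clip(vox, 0.0, None)

    img = DynamicImage(vox, spec.voxel_size, sched)
    truth = PhantomTruth(
        schedule=sched, fine_times=tgrid, arterial_fine=arterial_fine,
        venous_fine=venous_fine, parent_plasma_fine=parent_fine,
        arterial=TimeActivityCurve(sched.mid_times, art_frames, "arterial"),
        venous=TimeActivityCurve(sched.mid_times, ven_frames, "venous"),
        input_function=input_fn, region_params=region_params,
        region_masks=region_masks, region_roles=region_roles,
        b2p=spec.b2p, hill=spec.hill)
    return img, truth


def synth_trues(img: DynamicImage, lam_per_min: float | None = None
                ) -> np.ndarray:
    """Synthesize per-frame trues as total FOV activity x duration x decay.

    The phantom has no list-mode data, so trues are proxied by the quantity
    they track on a real scanner: detected true coincidences per frame.
    """
    from .kinetics import F18_LAMBDA_PER_MIN, decay_factor
    lam = F18_LAMBDA_PER_MIN if lam_per_min is None else lam_per_min
    total = img.voxels.sum(axis=(0, 1, 2)) * img.voxel_volume_ml
    dc = decay_factor(img.schedule.mid_times / 60.0, lam)
    return np.maximum(total * img.schedule.durations * dc, 0.0)
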