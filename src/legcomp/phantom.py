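"""Synthetic multi-contrast lower-extremity phantoms with ground-truth labels.

Each axial slice contains two roughly elliptical legs (mild per-slice
eccentricity jitter avoids trivially circular tissue outlines), each built
from a thin skin rim, a subcutaneous adipose tissue (SAT) annulus, a muscle
interior, one or two circular bones with fat-bright marrow, and optional thin
intramuscular fat (IMAT) arcs.  Cross-sections taper from the ankle (small
radius, two bones: tibia/fibula analog) to the thigh (large radius, one bone:
femur analog).

Contrast synthesis is complementary: the fat-weighted image is bright on
SAT/marrow/IMAT and dark on muscle, the water-weighted image is bright on
muscle, and the in-phase image is bright over the whole leg.  Skin is given a
sub-threshold water intensity (dermis is relatively dark on gradient-echo
water images), so the water foreground is muscle alone.  A smooth
multiplicative bias field (in-plane Gaussian shading plus a linear
slice-axis ramp, mimicking shim imperfection and isocenter drop-off) and
additive Gaussian noise perturb all three contrasts; truth labels are
returned unperturbed.

A "lipedema-like" phantom thickens the SAT annulus and expands the leg
radius by the same increment, leaving the muscle compartment unchanged --
disproportionate subcutaneous fat deposition with preserved musculature.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .volume_io import CSEVolume, save_cse_volume, save_nifti

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "iter_cohort",
    "save_phantom",
    "TRUTH_LABELS",
]

# nominal tissue intensities (arbitrary units, bright tissue = 1)
FAT_BRIGHT = 1.0
WATER_BRIGHT = 1.0
IN_PHASE_BRIGHT = 1.0
TISSUE_DIM = 0.08      # off-resonant tissue residual signal
SKIN_WATER = 0.15      # dermis on gradient-echo water images: short T2*, near-residual

# label volume encoding used when truth is written to disk
TRUTH_LABELS = {"skin": 1, "sat": 2, "muscle": 3, "marrow": 4, "imat": 5}


def _linear_profile(n: int, start: float, stop: float) -> np.ndarray:
    return np.linspace(start, stop, n)


@dataclass
class PhantomSpec:
    """Parametric description of a two-leg phantom volume.

    Profiles are per-slice arrays ordered inferior (ankle) -> superior
    (thigh); ``None`` selects the default tapering geometry.  All in-plane
    dimensions are in pixels; ``voxel_spacing`` is (row, col, slice) mm.
    """

    n_slices: int = 60
    in_plane_shape: tuple[int, int] = (96, 192)
    voxel_spacing: tuple[float, float, float] = (2.07, 1.35, 3.0)
    leg_separation: float = 96.0
    leg_radius_profile: np.ndarray | None = None        # default 22 -> 30 px
    sat_thickness_profile: np.ndarray | None = None     # default 6 -> 9 px
    skin_thickness: float = 1.0
    n_bones_profile: np.ndarray | None = None           # default 2 (calf half), 1 (thigh half)
    bone_radius: float = 3.0
    imat_streak_count: int = 2
    imat_streak_width: float = 2.0
    bias_field_amplitude: float = 0.3
    noise_sigma: float = 0.05
    seed: int = 0
    group_label: str = "control-like"

    def resolved(self) -> "PhantomSpec":
        """Return a copy with default profiles filled in."""
        n = self.n_slices
        out = replace(self)
        if out.leg_radius_profile is None:
            out.leg_radius_profile = _linear_profile(n, 22.0, 30.0)
        if out.sat_thickness_profile is None:
            out.sat_thickness_profile = _linear_profile(n, 6.0, 9.0)
        if out.n_bones_profile is None:
            out.n_bones_profile = np.where(np.arange(n) < n // 2, 2, 1)
        out.leg_radius_profile = np.asarray(out.leg_radius_profile, dtype=float)
        out.sat_thickness_profile = np.asarray(out.sat_thickness_profile, dtype=float)
        out.n_bones_profile = np.asarray(out.n_bones_profile, dtype=int)
        return out

    def validate(self) -> None:
        s = self.resolved()
        if s.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if any(len(p) != s.n_slices for p in (
                s.leg_radius_profile, s.sat_thickness_profile, s.n_bones_profile)):
            raise ValueError("per-slice profiles must have length n_slices")
        if min(s.in_plane_shape) < 8:
            raise ValueError("in-plane grid too small")
        if not (0.0 <= s.bias_field_amplitude < 1.0):
            raise ValueError("bias_field_amplitude must be in [0, 1)")
        if s.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if s.skin_thickness < 0 or s.bone_radius <= 0 or s.leg_separation <= 0:
            raise ValueError("geometric dimensions must be positive")
        rows, cols = s.in_plane_shape
        ecc_min = 0.80  # smallest column/row semi-axis ratio used by the jitter
        for k in range(s.n_slices):
            a = float(s.leg_radius_profile[k])
            t = float(s.sat_thickness_profile[k])
            if a <= 0 or t < 0:
                raise ValueError(f"slice {k}: non-positive leg radius or negative SAT thickness")
            a_in = a - s.skin_thickness - t
            b_in = a * ecc_min - s.skin_thickness - t
            need = 2 * s.bone_radius + 4 if s.n_bones_profile[k] >= 2 else s.bone_radius + 2
            if a_in < need or b_in < s.bone_radius + 2:
                raise ValueError(
                    f"slice {k}: skin + SAT + bone geometry does not fit inside "
                    f"leg radius {a:.1f} px (muscle semi-axes {a_in:.1f} x {b_in:.1f})"
                )
            if a >= rows / 2 - 1:
                raise ValueError(f"slice {k}: leg radius {a:.1f} px exceeds the row extent")
            if a + s.leg_separation / 2 >= cols / 2:
                raise ValueError(f"slice {k}: legs do not fit side by side in {cols} columns")


@dataclass
class PhantomTruth:
    """Ground-truth tissue labels on the phantom grid (mutually exclusive)."""

    leg: np.ndarray
    skin: np.ndarray
    sat: np.ndarray
    muscle: np.ndarray
    marrow: np.ndarray
    imat: np.ndarray
    group_label: str = "control-like"

    def tissue_masks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in TRUTH_LABELS}

    def label_volume(self) -> np.ndarray:
        """Single uint8 label map using :data:`TRUTH_LABELS` codes."""
        out = np.zeros(self.leg.shape, dtype=np.uint8)
        for name, code in TRUTH_LABELS.items():
            out[getattr(self, name)] = code
        return out


def _ellipse(rr: np.ndarray, cc: np.ndarray, r0: float, c0: float,
             a: float, b: float) -> np.ndarray:
    if a <= 0 or b <= 0:
        return np.zeros(rr.shape, dtype=bool)
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _rasterize_slice(spec: PhantomSpec, k: int, ecc: float, arc_phases: np.ndarray,
                     rr: np.ndarray, cc: np.ndarray) -> dict[str, np.ndarray]:
    rows, cols = spec.in_plane_shape
    r0 = rows / 2.0
    a_out = float(spec.leg_radius_profile[k])
    t = float(spec.sat_thickness_profile[k])
    skin_t = spec.skin_thickness
    shape = (rows, cols)
    masks = {name: np.zeros(shape, dtype=bool) for name in
             ("leg", "skin", "sat", "muscle", "marrow", "imat")}
    for leg_i, c0 in enumerate((cols / 2.0 - spec.leg_separation / 2.0,
                                cols / 2.0 + spec.leg_separation / 2.0)):
        b_out = a_out * ecc
        leg = _ellipse(rr, cc, r0, c0, a_out, b_out)
        inner_skin = _ellipse(rr, cc, r0, c0, a_out - skin_t, b_out - skin_t)
        a_in, b_in = a_out - skin_t - t, b_out - skin_t - t
        muscle_el = _ellipse(rr, cc, r0, c0, a_in, b_in)
        masks["leg"] |= leg
        masks["skin"] |= leg & ~inner_skin
        masks["sat"] |= inner_skin & ~muscle_el
        muscle = muscle_el.copy()
        # IMAT: thin arcs on the 0.6 iso-ellipse, in the left/right sectors
        # away from the bones (which sit on the anterior-posterior axis)
        if spec.imat_streak_count > 0 and spec.imat_streak_width > 0:
            rho = np.sqrt(((rr - r0) / a_in) ** 2 + ((cc - c0) / b_in) ** 2)
            theta = np.arctan2((rr - r0) / a_in, (cc - c0) / b_in)
            half_w = spec.imat_streak_width / (2.0 * min(a_in, b_in))
            band = np.abs(rho - 0.6) <= half_w
            arcs = np.zeros(shape, dtype=bool)
            for s_i in range(min(spec.imat_streak_count, 2)):
                center = (0.0 if s_i == 0 else np.pi) + arc_phases[leg_i * 2 + s_i]
                d = np.angle(np.exp(1j * (theta - center)))
                arcs |= band & (np.abs(d) <= np.pi / 6)
            imat = arcs & muscle_el
            masks["imat"] |= imat
            muscle &= ~imat
        # bones: marrow discs along the anterior-posterior (row) axis
        n_b = int(spec.n_bones_profile[k])
        offs = [0.0] if n_b <= 1 else [-(spec.bone_radius + 2), spec.bone_radius + 2]
        for off in offs[:max(n_b, 0)]:
            marrow = _ellipse(rr, cc, r0 + off, c0, spec.bone_radius, spec.bone_radius)
            masks["marrow"] |= marrow
            masks["imat"] &= ~marrow
            muscle &= ~marrow
        masks["muscle"] |= muscle
    return masks


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative field in (0, 1]: Gaussian in-plane shading + slice ramp."""
    rows, cols = spec.in_plane_shape
    n = spec.n_slices
    rr, cc = np.indices((rows, cols))
    # bump center jittered around the image center; shading grows outward
    cr = rows / 2.0 + rng.uniform(-0.1, 0.1) * rows
    ccen = cols / 2.0 + rng.uniform(-0.1, 0.1) * cols
    sigma = 0.45 * min(rows, cols)
    bump = np.exp(-((rr - cr) ** 2 + (cc - ccen) ** 2) / (2.0 * sigma ** 2))
    f_xy = 1.0 - bump  # 0 at the bump center, -> 1 at the periphery
    ramp = np.zeros(n) if n == 1 else np.arange(n) / (n - 1.0)
    f = 0.5 * f_xy[None, :, :] + 0.5 * ramp[:, None, None]
    return 1.0 - spec.bias_field_amplitude * f


def generate_phantom(spec: PhantomSpec) -> tuple[CSEVolume, PhantomTruth]:
    """Rasterize a phantom volume and synthesize its three contrasts.

    Identical spec (including seed) yields bit-identical output.  A spec
    whose tissues do not fit raises ``ValueError`` naming the first
    offending slice.
    """
    spec.validate()
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.in_plane_shape
    n = spec.n_slices
    rr, cc = np.indices((rows, cols))

    # per-slice shape jitter, drawn before any intensity randomness
    eccs = rng.uniform(0.80, 0.90, size=n)
    arc_phases = rng.uniform(-np.pi / 12, np.pi / 12, size=(n, 4))

    shape = (n, rows, cols)
    truth = {name: np.zeros(shape, dtype=bool) for name in
             ("leg", "skin", "sat", "muscle", "marrow", "imat")}
    for k in range(n):
        slice_masks = _rasterize_slice(spec, k, eccs[k], arc_phases[k], rr, cc)
        for name, m in slice_masks.items():
            truth[name][k] = m

    fat_fg = truth["sat"] | truth["marrow"] | truth["imat"]
    dim = truth["muscle"] | truth["skin"]
    fat = FAT_BRIGHT * fat_fg + TISSUE_DIM * dim
    water = WATER_BRIGHT * truth["muscle"] + SKIN_WATER * truth["skin"] + TISSUE_DIM * fat_fg
    in_phase = IN_PHASE_BRIGHT * truth["leg"].astype(float)

    bias = _bias_field(spec, rng)
    contrasts = []
    for img in (fat, water, in_phase):
        img = img * bias
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
        contrasts.append(np.clip(img, 0.0, None).astype(np.float32))

    volume = CSEVolume(contrasts[0], contrasts[1], contrasts[2], spec.voxel_spacing)
    return volume, PhantomTruth(group_label=spec.group_label, **truth)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_spec(base: PhantomSpec, group: str, sat_multiplier: float,
                  rng: np.random.Generator) -> PhantomSpec:
    # Between-subject anthropometric variability: a body-size scale factor
    # multiplies leg radius and SAT thickness together (height/frame spread;
    # it dominates circumference variance but cancels out of the
    # SAT-to-muscle ratio), plus independent SAT-thickness and leg-shape
    # jitter.  The resulting dispersion is of the order printed for real
    # cohorts (circumference coefficient of variation around 10-15%, SAT
    # volume considerably wider).
    body_scale = rng.uniform(0.85, 1.15)
    shape_jit = rng.uniform(0.97, 1.03)
    sat_jit = rng.uniform(0.85, 1.15)
    seed = int(rng.integers(0, 2**31 - 1))
    base = base.resolved()
    radius = base.leg_radius_profile * body_scale * shape_jit
    sat = base.sat_thickness_profile * body_scale * sat_jit
    if group == "lipedema-like":
        sat_new = sat * sat_multiplier
        radius = radius + (sat_new - sat)  # fat deposits outward; muscle preserved
        sat = sat_new
    return replace(base, leg_radius_profile=radius, sat_thickness_profile=sat,
                   seed=seed, group_label=group)


def iter_cohort(n_control: int, n_lipedema: int, base_spec: PhantomSpec | None = None,
                sat_multiplier: float = 1.75, seed: int = 0,
                ) -> Iterator[tuple[PhantomSpec, CSEVolume, PhantomTruth]]:
    """Lazily generate a two-group phantom cohort (controls first).

    Per-subject multiplicative jitter is applied to the leg radius and SAT
    thickness; lipedema-like subjects additionally get the SAT-thickness
    multiplier with a matching outward leg-radius expansion.
    """
    if n_control < 1 or n_lipedema < 1:
        raise ValueError("both group sizes must be >= 1")
    if sat_multiplier <= 0:
        raise ValueError("sat_multiplier must be positive")
    base = (base_spec or PhantomSpec()).resolved()
    rng = np.random.default_rng(seed)
    groups = ["control-like"] * n_control + ["lipedema-like"] * n_lipedema
    for group in groups:
        spec = _subject_spec(base, group, sat_multiplier, rng)
        vol, truth = generate_phantom(spec)
        yield spec, vol, truth


def generate_cohort(n_control: int, n_lipedema: int, base_spec: PhantomSpec | None = None,
                    sat_multiplier: float = 1.75, seed: int = 0,
                    ) -> list[tuple[CSEVolume, PhantomTruth]]:
    """Materialized cohort; see :func:`iter_cohort` for the construction."""
    return [(vol, truth) for _, vol, truth in
            iter_cohort(n_control, n_lipedema, base_spec, sat_multiplier, seed)]


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def save_phantom(volume: CSEVolume, truth: PhantomTruth, out_dir: str | Path,
                 spec: PhantomSpec | None = None) -> None:
    """Write contrasts, a truth label volume and (optionally) the spec as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_cse_volume(volume, out)
    save_nifti(truth.label_volume(), volume.voxel_spacing, out / "truth.nii.gz")
    save_nifti(truth.leg.astype(np.uint8), volume.voxel_spacing, out / "truth_leg.nii.gz")
    if spec is not None:
        d = asdict(spec.resolved())
        for key in ("leg_radius_profile", "sat_thickness_profile", "n_bones_profile"):
            d[key] = np.asarray(d[key]).tolist()
        (out / "spec.json").write_text(json.dumps(d, indent=2))


def save_cohort(n_control: int, n_lipedema: int, out_dir: str | Path,
                base_spec: PhantomSpec | None = None, sat_multiplier: float = 1.75,
                seed: int = 0) -> Path:
    """Generate a cohort to ``out_dir/subject_XX/`` with a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "group", "seed", "path"])
        for i, (spec, vol, truth) in enumerate(
                iter_cohort(n_control, n_lipedema, base_spec, sat_multiplier, seed)):
            sub = f"subject_{i:02d}"
            save_phantom(vol, truth, out / sub, spec=spec)
            writer.writerow([sub, spec.group_label, spec.seed, sub])
    return manifest
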