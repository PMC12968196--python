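"""Seeded digital phantoms with known ground truth.

The phantom stands in for a co-registered patient dataset: a brain mask,
per-hemisphere putamen masks, cortical/subcortical ROI blobs, ventricle- and
vessel-like critical structures, planted anisotropic fiber bundles joining
chosen ROIs to chosen putamen quadrants, a per-voxel tensor field (and
optionally the synthesized DWI signal), AC/PC/superior landmarks, and
frontal/occipital entry-target pairs per hemisphere.  Everything is
deterministic given the spec seed, and the planted (roi, quadrant,
hemisphere) connection table is recorded as ground truth.

Bundles are swept tubes around quadratic-Bezier (or piecewise-linear)
centerlines; tensors inside a tube are axially symmetric with the principal
eigenvector along the local tangent, which gives closed-form control of
fractional anisotropy (see :func:`axially_symmetric_tensor`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .acpc import SEGMENT_CODES, build_acpc_frame, classify_points
from .tractography import TensorField
from .volume import Volume, write_volume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "RoiSpec",
    "BundleSpec",
    "generate_phantom",
    "synthesize_dwi",
    "axially_symmetric_tensor",
    "electrostatic_directions",
    "load_gradient_table",
    "write_phantom",
]

HEMI_SIGN = {"right": 1.0, "left": -1.0}


# --------------------------------------------------------------------------
# spec dataclasses

@dataclass(frozen=True)
class RoiSpec:
    """Spherical cortical/subcortical ROI blob (center in right-hemisphere
    mm coordinates; mirrored in x for the left hemisphere)."""

    name: str
    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class BundleSpec:
    """Anisotropic tube from a putamen quadrant to a named ROI.

    ``waypoints`` are right-hemisphere mm points from the in-putamen end to
    the in-ROI end; three points are treated as a quadratic Bezier,
    otherwise the centerline is piecewise linear.
    """

    roi: str
    target_quadrant: str
    radius: float
    waypoints: tuple[tuple[float, float, float], ...]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject.

    Defaults emulate the study's acquisition geometry: 2 mm isotropic
    voxels on a 64^3 grid, 64 diffusion directions at b = 1000 s/mm^2 (plus
    one b = 0 volume), bundle FA 0.7 over an FA 0.05 background, and
    frontal (anterior-superior) vs occipital (posterior) entry points per
    hemisphere.  ``jitter_mm`` adds seeded per-subject anatomical
    variability (putamen/ROI/vessel/entry positions) so a cohort of
    phantoms is not 20 copies of one brain.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    hemispheres: tuple[str, ...] = ("left", "right")
    ac: tuple[float, float, float] = (0.0, 4.0, 0.0)
    pc: tuple[float, float, float] = (0.0, -22.0, 0.0)
    ih: tuple[float, float, float] = (0.0, 4.0, 40.0)
    brain_center: tuple[float, float, float] = (0.0, -2.0, 0.0)
    brain_semiaxes: tuple[float, float, float] = (50.0, 55.0, 45.0)
    putamen_center: tuple[float, float, float] = (24.0, 4.0, 0.0)
    putamen_semiaxes: tuple[float, float, float] = (8.0, 14.0, 10.0)
    cortical_rois: tuple[RoiSpec, ...] = (
        RoiSpec("SMA", (12.0, -4.0, 38.0), 7.0),
        RoiSpec("amygdala", (26.0, -4.0, -30.0), 7.0),
    )
    bundles: tuple[BundleSpec, ...] = (
        BundleSpec("SMA", "superior-posterior", 3.0,
                   ((24.0, -4.0, 6.0), (24.0, -4.0, 24.0), (12.0, -4.0, 38.0))),
        BundleSpec("amygdala", "inferior-posterior", 3.0,
                   ((24.0, -4.0, -6.0), (26.0, -4.0, -18.0), (26.0, -4.0, -30.0))),
    )
    ventricle: dict | None = field(default_factory=lambda: dict(
        x_halfwidth=6.0, y_range=(-34.0, 10.0), z_range=(-2.0, 22.0)))
    vessels: tuple[dict, ...] = (
        dict(name="vessel_frontal", x=16.0, y=10.0, radius=2.0, z_range=(-10.0, 30.0)),
        dict(name="vessel_occipital", x=27.0, y=-30.0, radius=2.0, z_range=(-10.0, 30.0)),
    )
    entry_frontal: tuple[float, float, float] = (18.0, 38.0, 24.0)
    entry_occipital: tuple[float, float, float] = (20.0, -48.0, 2.0)
    # per-approach targets, each placed at the far end of the
    # superior-posterior segment along its approach so the straight path
    # maximizes in-segment length (the planning principle of the study)
    target_frontal: tuple[float, float, float] = (24.0, -8.0, 0.0)
    target_occipital: tuple[float, float, float] = (24.0, 2.0, 4.0)
    fa_bundle: float = 0.7
    fa_background: float = 0.05
    mean_diffusivity: float = 0.7e-3  # mm^2/s
    n_directions: int = 64
    b_value: float = 1000.0
    s0: float = 100.0
    noise_sigma: float = 0.0
    jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.allclose(self.ac, self.pc):
            raise ValueError("AC and PC must differ")
        roi_names = {r.name for r in self.cortical_rois}
        for b in self.bundles:
            if b.roi not in roi_names:
                raise ValueError(f"bundle references unknown ROI {b.roi!r}")
            if b.target_quadrant not in SEGMENT_CODES:
                raise ValueError(f"unknown quadrant {b.target_quadrant!r}")


@dataclass
class Phantom:
    """One generated subject with all masks, tensors and ground truth."""

    spec: PhantomSpec
    brain_mask: Volume
    putamen_masks: dict[str, Volume]
    roi_masks: dict[tuple[str, str], Volume]          # (roi name, hemisphere)
    critical_masks: dict[str, Volume]
    tensor_field: TensorField
    landmarks: dict[str, np.ndarray]
    trajectories: dict[tuple[str, str], dict[str, np.ndarray]]  # (hemi, approach)
    truth: pd.DataFrame                               # roi, quadrant, hemisphere
    dwi_signal: np.ndarray | None = None
    bvecs: np.ndarray | None = None
    bvals: np.ndarray | None = None


# --------------------------------------------------------------------------
# tensors and gradients

def axially_symmetric_tensor(fa: float, md: float, axis: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 tensor with the given FA, mean diffusivity and
    principal axis.

    With eigenvalues (md(1+2d), md(1-d), md(1-d)) the FA is
    ``3d / sqrt(3 + 6d^2)``, which inverts to ``d = fa / sqrt(3 - 2 fa^2)``.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must lie in [0, 1)")
    d = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    t = np.asarray(axis, dtype=float)
    t = t / np.linalg.norm(t)
    return md * ((1.0 - d) * np.eye(3) + 3.0 * d * np.outer(t, t))


def electrostatic_directions(n: int = 64, seed: int = 7, n_iter: int = 500,
                             step: float = 0.05) -> np.ndarray:
    """n approximately uniformly spread unit vectors (antipodally
    symmetric electrostatic repulsion), used once to build the shipped
    gradient-table fixture."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]
            d2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(d2, np.inf)
            d2[d2 < 1e-12] = np.inf
            force += np.sum(diff / (d2[..., None] ** 1.5), axis=1)
        v = v + step * force / n
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def load_gradient_table() -> tuple[np.ndarray, np.ndarray]:
    """Shipped FSL-style gradient table: 1 b=0 volume + 64 directions at
    b = 1000 s/mm^2.  Returns (bvecs (65, 3), bvals (65,))."""
    data_dir = resources.files("cedplan") / "data"
    bvecs = np.loadtxt(str(data_dir / "gradients64.bvec")).T
    bvals = np.loadtxt(str(data_dir / "gradients64.bval")).ravel()
    return bvecs, bvals


def synthesize_dwi(tensor_field: TensorField, gradients: np.ndarray,
                   bvals: np.ndarray | float, s0: float = 100.0,
                   sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Monoexponential single-tensor forward model, S_i = S0 exp(-b g'Dg),
    with optional Rician noise (two Gaussian quadrature channels).

    ``bvals`` may be one scalar shared by all directions or one value per
    row of ``gradients`` (zero rows give b = 0 volumes).  Voxels outside
    the field's validity mask emit zero signal (noise is still added so a
    noisy background looks like magnitude MRI).
    """
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("gradients must be (n, 3)")
    b = np.broadcast_to(np.asarray(bvals, dtype=float), (g.shape[0],)).copy()
    if np.max(b) <= 0:
        raise ValueError("b-value must be positive")
    if np.any(b < 0):
        raise ValueError("negative b-value")
    weighted = b > 0
    if weighted.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted directions required")
    if np.linalg.matrix_rank(g[weighted]) < 3:
        raise ValueError("gradient directions are collinear")
    comp = tensor_field.components
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # g' D g from the 6 unique components, vectorized over directions
    quad = (
        comp[..., 0, None] * gx**2 + comp[..., 1, None] * gy**2
        + comp[..., 2, None] * gz**2 + 2 * comp[..., 3, None] * gx * gy
        + 2 * comp[..., 4, None] * gx * gz + 2 * comp[..., 5, None] * gy * gz
    )
    signal = s0 * np.exp(-b * quad)
    signal[~tensor_field.valid] = 0.0
    if sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return signal


# --------------------------------------------------------------------------
# geometry helpers

def _bezier(waypoints: np.ndarray, n: int = 160) -> np.ndarray:
    """Centerline samples: quadratic Bezier for 3 waypoints, else
    piecewise-linear interpolation."""
    w = np.asarray(waypoints, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    if len(w) == 3:
        return (1 - t) ** 2 * w[0] + 2 * (1 - t) * t * w[1] + t**2 * w[2]
    # piecewise linear, arc-length parameterized per segment
    segs = [np.linspace(w[i], w[i + 1], max(2, n // (len(w) - 1)), axis=0) for i in range(len(w) - 1)]
    return np.vstack(segs)


def _ellipsoid_mask(coords: np.ndarray, center, semiaxes) -> np.ndarray:
    rel = (coords - np.asarray(center)) / np.asarray(semiaxes)
    return np.sum(rel * rel, axis=-1) <= 1.0


def _default_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= spec.voxel_size
    # grid centered on the world origin
    aff[:3, 3] = -spec.voxel_size * (np.asarray(spec.grid_shape) // 2)
    return aff


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one subject deterministically from the spec (and its seed).

    Raises a configuration error if a planted bundle never enters its
    stated putamen quadrant, if a putamen does not intersect all four
    quadrants, or if any labeled structure leaks outside the brain mask.
    """
    rng = np.random.default_rng(spec.seed)
    jit = lambda k=3: rng.uniform(-spec.jitter_mm, spec.jitter_mm, k) if spec.jitter_mm > 0 else np.zeros(k)

    affine = _default_affine(spec)
    shape = tuple(spec.grid_shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    coords = idx @ affine[:3, :3].T + affine[:3, 3]  # voxel centers, world mm

    brain = _ellipsoid_mask(coords, spec.brain_center, spec.brain_semiaxes)
    brain_vol = Volume(brain.astype(np.uint8), affine)

    ac, pc, ih = (np.asarray(p, float) for p in (spec.ac, spec.pc, spec.ih))
    frame = build_acpc_frame(ac, pc, ih)

    # per-subject anatomical jitter (mirror-symmetric so hemispheres match)
    put_jit = jit()
    roi_jit = {r.name: jit() for r in spec.cortical_rois}
    vessel_jit = {v["name"]: float(jit(1)[0] * 2.0) for v in spec.vessels}
    entry_jit = {"frontal": jit(), "occipital": jit()}

    def mirrored(p, hemi):
        q = np.asarray(p, dtype=float).copy()
        q[0] *= HEMI_SIGN[hemi]
        return q

    putamen_masks: dict[str, Volume] = {}
    roi_masks: dict[tuple[str, str], Volume] = {}
    bundle_tubes: list[tuple[str, np.ndarray, np.ndarray]] = []  # hemi, mask, tangents idx
    tangent_store: list[np.ndarray] = []
    truth_rows = []

    for hemi in spec.hemispheres:
        s = HEMI_SIGN[hemi]
        pcen = mirrored(np.asarray(spec.putamen_center) + put_jit, hemi)
        pmask = _ellipsoid_mask(coords, pcen, spec.putamen_semiaxes) & brain
        if not pmask.any():
            raise ValueError(f"empty putamen mask ({hemi})")
        codes = classify_points(coords[pmask], frame)
        if len(np.unique(codes)) != 4:
            raise ValueError(f"putamen ({hemi}) does not intersect all four AC-PC quadrants")
        putamen_masks[hemi] = Volume(pmask.astype(np.uint8), affine)

        for r in spec.cortical_rois:
            rcen = mirrored(np.asarray(r.center) + roi_jit[r.name], hemi)
            rmask = _ellipsoid_mask(coords, rcen, (r.radius,) * 3) & brain
            roi_masks[(r.name, hemi)] = Volume(rmask.astype(np.uint8), affine)

        for b in spec.bundles:
            wpts = np.array([mirrored(np.asarray(w) + (put_jit if i == 0 else roi_jit[b.roi]), hemi)
                             for i, w in enumerate(b.waypoints)])
            line = _bezier(wpts)
            tangents = np.gradient(line, axis=0)
            tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
            tree = cKDTree(line)
            flat = coords.reshape(-1, 3)
            d, nearest = tree.query(flat, workers=-1)
            tube = (d.reshape(shape) <= b.radius) & brain
            # validation: tube must reach its stated quadrant inside the putamen
            overlap = tube & pmask
            if not overlap.any():
                raise ValueError(f"bundle {b.roi}->{b.target_quadrant} never enters the putamen ({hemi})")
            over_codes = classify_points(coords[overlap], frame)
            if SEGMENT_CODES[b.target_quadrant] not in over_codes:
                raise ValueError(
                    f"bundle {b.roi}->{b.target_quadrant} never enters its stated quadrant ({hemi})")
            if not (tube & (roi_masks[(b.roi, hemi)].data > 0)).any():
                raise ValueError(f"bundle {b.roi} does not terminate inside its ROI ({hemi})")
            bundle_tubes.append((hemi, tube, nearest.reshape(shape)))
            tangent_store.append(tangents)
            truth_rows.append(dict(roi=b.roi, quadrant=b.target_quadrant, hemisphere=hemi))

    # critical structures (ventricle slab + vessel cylinders), clipped to brain
    critical_masks: dict[str, Volume] = {}
    if spec.ventricle is not None:
        vent = spec.ventricle
        vent_mask = (
            (np.abs(coords[..., 0]) <= vent["x_halfwidth"])
            & (coords[..., 1] >= vent["y_range"][0]) & (coords[..., 1] <= vent["y_range"][1])
            & (coords[..., 2] >= vent["z_range"][0]) & (coords[..., 2] <= vent["z_range"][1])
            & brain
        )
        critical_masks["ventricle"] = Volume(vent_mask.astype(np.uint8), affine)
    for v in spec.vessels:
        m = np.zeros(shape, dtype=bool)
        for hemi in spec.hemispheres:
            s = HEMI_SIGN[hemi]
            ax_x, ax_y = s * (v["x"] + vessel_jit[v["name"]]), v["y"]
            dist2 = (coords[..., 0] - ax_x) ** 2 + (coords[..., 1] - ax_y) ** 2
            m |= (dist2 <= v["radius"] ** 2) & (coords[..., 2] >= v["z_range"][0]) \
                & (coords[..., 2] <= v["z_range"][1]) & brain
        critical_masks[v["name"]] = Volume(m.astype(np.uint8), affine)

    # tensor field: isotropic-ish background in the brain, tube tensors on top
    md, fa_bg = spec.mean_diffusivity, spec.fa_background
    bg = axially_symmetric_tensor(fa_bg, md, np.array([1.0, 0.0, 0.0]))
    comp = np.zeros(shape + (6,), dtype=float)
    bg6 = np.array([bg[0, 0], bg[1, 1], bg[2, 2], bg[0, 1], bg[0, 2], bg[1, 2]])
    comp[brain] = bg6
    d_frac = spec.fa_bundle / np.sqrt(3.0 - 2.0 * spec.fa_bundle**2)
    for (hemi, tube, nearest), tangents in zip(bundle_tubes, tangent_store):
        t = tangents[nearest[tube]]  # (n_tube, 3) local tangent
        outer = np.einsum("ni,nj->nij", t, t)
        mats = md * ((1.0 - d_frac) * np.eye(3) + 3.0 * d_frac * outer)
        comp[tube] = np.stack(
            [mats[:, 0, 0], mats[:, 1, 1], mats[:, 2, 2],
             mats[:, 0, 1], mats[:, 0, 2], mats[:, 1, 2]], axis=-1)
    tensor_field = TensorField(components=comp, affine=affine, valid=brain)

    trajectories = {}
    for hemi in spec.hemispheres:
        for approach, base, tgt_base in (
            ("frontal", spec.entry_frontal, spec.target_frontal),
            ("occipital", spec.entry_occipital, spec.target_occipital),
        ):
            entry = mirrored(np.asarray(base) + entry_jit[approach], hemi)
            tgt = mirrored(np.asarray(tgt_base) + put_jit, hemi)
            trajectories[(hemi, approach)] = {"entry": entry, "target": tgt}

    truth = pd.DataFrame(truth_rows, columns=["roi", "quadrant", "hemisphere"])
    return Phantom(
        spec=spec,
        brain_mask=brain_vol,
        putamen_masks=putamen_masks,
        roi_masks=roi_masks,
        critical_masks=critical_masks,
        tensor_field=tensor_field,
        landmarks={"ac": ac, "pc": pc, "ih": ih},
        trajectories=trajectories,
        truth=truth,
    )


def attach_dwi(phantom: Phantom, sigma: float | None = None, seed: int | None = None) -> Phantom:
    """Synthesize and attach the DWI signal using the shipped gradient
    table and the spec's S0 / noise level (overridable)."""
    bvecs, bvals = load_gradient_table()
    spec = phantom.spec
    sig = synthesize_dwi(
        phantom.tensor_field, bvecs, bvals, s0=spec.s0,
        sigma=spec.noise_sigma if sigma is None else sigma,
        seed=spec.seed if seed is None else seed,
    )
    phantom.dwi_signal, phantom.bvecs, phantom.bvals = sig, bvecs, bvals
    return phantom


def write_phantom(phantom: Phantom, out_dir) -> Path:
    """Write the phantom as NIfTI volumes + a JSON manifest (truth table,
    landmarks, entries/targets, seed) + FSL-style bvec/bval files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.brain_mask, out / "brain_mask.nii.gz")
    for hemi, v in phantom.putamen_masks.items():
        write_volume(v, out / f"putamen_{hemi}.nii.gz")
    for (name, hemi), v in phantom.roi_masks.items():
        write_volume(v, out / f"roi_{name}_{hemi}.nii.gz")
    for name, v in phantom.critical_masks.items():
        write_volume(v, out / f"critical_{name}.nii.gz")
    if phantom.bvecs is not None:
        np.savetxt(out / "dwi.bvec", phantom.bvecs.T, fmt="%.8f")
        np.savetxt(out / "dwi.bval", phantom.bvals[None, :], fmt="%.1f")
    manifest = {
        "seed": phantom.spec.seed,
        "voxel_size": phantom.spec.voxel_size,
        "landmarks": {k: list(map(float, v)) for k, v in phantom.landmarks.items()},
        "trajectories": [
            {"hemisphere": h, "approach": a,
             "entry": list(map(float, t["entry"])), "target": list(map(float, t["target"]))}
            for (h, a), t in phantom.trajectories.items()
        ],
        "truth": phantom.truth.to_dict(orient="records"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
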