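"""Synthetic tight-junction data with known ground truth.

Everything downstream of this module (functional assays, widefield
quantification, SMLM localization, spatial statistics) is validated by
parameter recovery against the generators defined here.  The generators
emulate the statistical structure of a single-monolayer tight-junction
experiment:

* a junction "belt" geometry — the cell–cell contact network of a
  confluent endothelial monolayer, modelled as the edge set of a Voronoi
  tessellation of random cell centres;
* fluorophore placements along the belt, either dispersed (uniform along
  arc length) or clustered (Thomas-style parent/offspring process);
* EMCCD blinking movies: per-frame Bernoulli ON states, integrated 2D
  Gaussian PSFs, Poisson shot noise amplified by the EM gain, Gaussian
  read noise and a constant baseline, written as 16-bit stacks;
* widefield immunofluorescence z-stacks with one in-focus slice and
  substrate-dependent background (glass < polycarbonate < polyester);
* transendothelial electrical resistance (TER) and FITC-dextran flux
  records with treatment effects of configurable size.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds and parameters give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf
from shapely.geometry import LineString, MultiPoint, box
from shapely.ops import voronoi_diagram

__all__ = [
    "JunctionGeometry",
    "ClusteringParams",
    "AcquisitionParams",
    "EffectParams",
    "GroundTruthMolecules",
    "FunctionalDataset",
    "generate_junction_network",
    "place_fluorophores",
    "place_colocalized_channels",
    "render_smlm_stack",
    "render_widefield_if",
    "generate_functional_dataset",
    "belt_mask",
    "save_ground_truth_csv",
    "write_parameter_sidecar",
]

Substrate = Literal["glass", "PC", "PE"]

#: Additive widefield background level (ADU) per substrate.  Coverglass has
#: the least autofluorescence, polyester filters the most.
SUBSTRATE_BACKGROUND_ADU: dict[str, float] = {"glass": 100.0, "PC": 300.0, "PE": 600.0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionGeometry:
    """Junction-belt network of a confluent monolayer.

    Parameters
    ----------
    field_size_nm:
        (width, height) of the simulated field in nm.
    belts:
        Polylines (each an ``(n, 2)`` float array of nm coordinates, n >= 2)
        tracing the cell–cell contact belts.
    n_cells:
        Number of cells whose contacts the belts represent.
    """

    field_size_nm: tuple[float, float]
    belts: tuple[np.ndarray, ...]
    n_cells: int

    def __post_init__(self) -> None:
        w, h = self.field_size_nm
        if w <= 0 or h <= 0:
            raise ValueError("field_size_nm must be positive")
        if not self.belts:
            raise ValueError("geometry has no belts")
        for belt in self.belts:
            if belt.ndim != 2 or belt.shape[0] < 2 or belt.shape[1] != 2:
                raise ValueError("each belt must be an (n>=2, 2) polyline")
            if belt.min() < -1e-6 or (belt[:, 0] > w + 1e-6).any() or (
                belt[:, 1] > h + 1e-6
            ).any():
                raise ValueError("belt vertex outside field")
        if self.total_belt_length_nm() <= 0:
            raise ValueError("total belt length must be positive")

    def total_belt_length_nm(self) -> float:
        return float(
            sum(np.hypot(*np.diff(b, axis=0).T).sum() for b in self.belts)
        )


@dataclass(frozen=True)
class ClusteringParams:
    """Placement statistics of labelled molecules along the belt.

    ``dispersed`` places molecules uniformly along belt arc length at
    ``linear_density_per_um``; ``clustered`` uses a Thomas process whose
    parents are uniform along the belt, with Poisson-distributed offspring
    counts and isotropic Gaussian offsets.  ``off_belt_fraction`` of all
    molecules are placed uniformly in the field instead (non-junctional
    background labelling).  The expected total count is
    ``belt_length_um * linear_density_per_um`` in both modes.
    """

    mode: Literal["dispersed", "clustered"] = "dispersed"
    linear_density_per_um: float = 10.0
    cluster_sigma_nm: float = 20.0
    mean_molecules_per_cluster: float = 8.0
    off_belt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.linear_density_per_um <= 0:
            raise ValueError("linear_density_per_um must be > 0")
        if self.mode == "clustered" and self.cluster_sigma_nm <= 0:
            raise ValueError("cluster_sigma_nm must be > 0 in clustered mode")
        if not 0 <= self.off_belt_fraction < 1:
            raise ValueError("off_belt_fraction must lie in [0, 1)")
        if self.mode not in ("dispersed", "clustered"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AcquisitionParams:
    """SMLM acquisition model.

    Defaults mirror a typical EMCCD super-resolution acquisition: 2000
    frames at 80 nm/px with EM gain 100.  ``psf_sigma_nm`` defaults to
    130 nm, a realistic width for a high-NA oil objective at 561–642 nm.
    Set ``shot_noise=False`` and ``read_noise_adu=0`` for noise-free
    renders (photon-conservation checks).
    """

    n_frames: int = 2000
    pixel_nm: float = 80.0
    psf_sigma_nm: float = 130.0
    photons_per_on_frame: float = 1000.0
    on_probability: float = 0.003
    em_gain: float = 100.0
    read_noise_adu: float = 10.0
    baseline_adu: float = 100.0
    bit_depth: int = 16
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.on_probability < 1:
            raise ValueError("on_probability must lie in [0, 1)")
        for name in ("pixel_nm", "psf_sigma_nm", "photons_per_on_frame", "em_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.read_noise_adu < 0 or self.baseline_adu < 0:
            raise ValueError("noise terms must be >= 0")


@dataclass(frozen=True)
class GroundTruthMolecules:
    """True fluorophore coordinates with cluster labels.

    ``cluster_id`` is -1 for molecules that do not belong to a cluster
    (dispersed placements and off-belt background).  ``colocalized_partner``
    maps each molecule to the index of its partner in the other channel's
    table, or -1 when it has none.
    """

    positions_nm: np.ndarray  # (n, 2)
    channel: str
    cluster_id: np.ndarray  # (n,) int
    colocalized_partner: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.positions_nm.ndim != 2 or self.positions_nm.shape[1] != 2:
            raise ValueError("positions_nm must be (n, 2)")
        if self.cluster_id.shape[0] != self.positions_nm.shape[0]:
            raise ValueError("cluster_id length mismatch")

    @property
    def n(self) -> int:
        return self.positions_nm.shape[0]


@dataclass(frozen=True)
class EffectParams:
    """Treatment-effect sizes for the functional (TER / flux) generator.

    Defaults encode a barrier-tightening dipeptide treatment: TER rises by
    a factor 1.30 after 1 h and 1.41 after 5 h relative to medium control,
    while 10 kDa dextran flux falls to 31.7% of control.  ``blank_ohm``
    holds the blank-filter resistance per substrate (polyester 121 Ω,
    polycarbonate 88 Ω) so blank subtraction is exercised downstream.
    """

    ter_fold_1h: float = 1.30
    ter_fold_5h: float = 1.41
    flux_fraction_of_control: float = 0.317
    replicate_cv: float = 0.1
    baseline_ter_ohm_cm2: float = 12.9
    blank_ohm: dict[str, float] = field(
        default_factory=lambda: {"PE": 121.0, "PC": 88.0}
    )
    area_cm2: float = 0.33

    def __post_init__(self) -> None:
        for name in ("ter_fold_1h", "ter_fold_5h", "flux_fraction_of_control",
                     "baseline_ter_ohm_cm2", "area_cm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass(frozen=True)
class FunctionalDataset:
    """Tables produced by :func:`generate_functional_dataset`."""

    ter: pd.DataFrame
    flux: pd.DataFrame
    standards: pd.DataFrame


# ---------------------------------------------------------------------------
# junction geometry
# ---------------------------------------------------------------------------


def generate_junction_network(
    n_cells: int,
    field_size_nm: Sequence[float],
    seed: int,
) -> JunctionGeometry:
    """Voronoi junction network of ``n_cells`` random cell centres.

    Cell centres are sampled uniformly in the field; the belts are the
    Voronoi edges clipped to the field rectangle.  Deterministic for a
    fixed seed.
    """
    if n_cells < 2:
        raise ValueError("cannot form junctions: need n_cells >= 2")
    w, h = float(field_size_nm[0]), float(field_size_nm[1])
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.0, 0.0], [w, h], size=(n_cells, 2))
    clip = box(0.0, 0.0, w, h)
    if n_cells == 2:
        # perpendicular bisector of the two centres, clipped to the field
        mid = pts.mean(axis=0)
        d = pts[1] - pts[0]
        perp = np.array([-d[1], d[0]])
        perp = perp / np.hypot(*perp)
        reach = 2.0 * (w + h)
        line = LineString([mid - reach * perp, mid + reach * perp])
        edges = line.intersection(clip)
    else:
        diagram = voronoi_diagram(
            MultiPoint([tuple(p) for p in pts]), envelope=clip, edges=True
        )
        edges = diagram.intersection(clip)
    belts: list[np.ndarray] = []
    geoms = getattr(edges, "geoms", [edges])
    for geom in geoms:
        if geom.is_empty or geom.geom_type != "LineString":
            continue
        arr = np.asarray(geom.coords, dtype=float)
        if arr.shape[0] >= 2 and np.hypot(*np.diff(arr, axis=0).T).sum() > 0:
            belts.append(np.clip(arr, [0, 0], [w, h]))
    return JunctionGeometry(field_size_nm=(w, h), belts=tuple(belts), n_cells=n_cells)


def _belt_segments(geometry: JunctionGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten belts to (starts, vectors, lengths) over all segments."""
    starts, vecs = [], []
    for belt in geometry.belts:
        starts.append(belt[:-1])
        vecs.append(np.diff(belt, axis=0))
    s = np.concatenate(starts)
    v = np.concatenate(vecs)
    lens = np.hypot(v[:, 0], v[:, 1])
    keep = lens > 0
    return s[keep], v[keep], lens[keep]


def _sample_on_belts(
    geometry: JunctionGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` points uniformly along belt arc length."""
    if n == 0:
        return np.empty((0, 2))
    starts, vecs, lens = _belt_segments(geometry)
    seg = rng.choice(len(lens), size=n, p=lens / lens.sum())
    t = rng.uniform(size=n)
    return starts[seg] + t[:, None] * vecs[seg]


# ---------------------------------------------------------------------------
# fluorophore placement
# ---------------------------------------------------------------------------


def place_fluorophores(
    geometry: JunctionGeometry,
    params: ClusteringParams,
    seed: int,
    channel: str = "ch0",
) -> GroundTruthMolecules:
    """Place molecules on the belt network with known clustering structure.

    The total count is Poisson with mean
    ``belt_length_um * linear_density_per_um`` in both modes, so dispersed
    and clustered placements are directly comparable at equal density.
    Positions are clipped to the field.
    """
    rng = np.random.default_rng(seed)
    length_um = geometry.total_belt_length_nm() / 1000.0
    expected = length_um * params.linear_density_per_um
    w, h = geometry.field_size_nm

    on_belt_expected = expected * (1.0 - params.off_belt_fraction)
    if params.mode == "dispersed":
        n_on = rng.poisson(on_belt_expected)
        pos = _sample_on_belts(geometry, n_on, rng)
        cid = np.full(n_on, -1, dtype=int)
    else:
        n_parents = rng.poisson(on_belt_expected / params.mean_molecules_per_cluster)
        parents = _sample_on_belts(geometry, n_parents, rng)
        counts = rng.poisson(params.mean_molecules_per_cluster, size=n_parents)
        cid = np.repeat(np.arange(n_parents), counts)
        offsets = rng.normal(0.0, params.cluster_sigma_nm, size=(cid.size, 2))
        pos = parents[cid] + offsets

    n_off = rng.poisson(expected * params.off_belt_fraction)
    off = rng.uniform([0.0, 0.0], [w, h], size=(n_off, 2))
    pos = np.vstack([pos, off]) if pos.size else off.reshape(-1, 2)
    cid = np.concatenate([cid, np.full(n_off, -1, dtype=int)])
    pos = np.clip(pos, [0.0, 0.0], [w, h])
    return GroundTruthMolecules(positions_nm=pos, channel=channel, cluster_id=cid)


def place_colocalized_channels(
    geometry: JunctionGeometry,
    params: ClusteringParams,
    coloc_fraction: float,
    seed: int,
    partner_sigma_nm: float = 20.0,
    channels: tuple[str, str] = ("chA", "chB"),
) -> tuple[GroundTruthMolecules, GroundTruthMolecules]:
    """Two-channel ground truth with a known colocalized fraction.

    Channel A is placed by :func:`place_fluorophores`.  A fraction
    ``coloc_fraction`` of A molecules (chosen without replacement) receive
    a channel-B partner offset by an isotropic Gaussian of
    ``partner_sigma_nm`` (default 20 nm, so true partners fall within a
    90 nm colocalization radius with probability > 0.99).  The remaining
    B molecules are unpaired background placed uniformly in the field.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mol_a = place_fluorophores(geometry, params, seed=int(rng.integers(2**31)),
                               channel=channels[0])
    n_a = mol_a.n
    n_partner = int(round(coloc_fraction * n_a))
    partner_of = rng.choice(n_a, size=n_partner, replace=False)
    offsets = rng.normal(0.0, partner_sigma_nm, size=(n_partner, 2))
    b_paired = mol_a.positions_nm[partner_of] + offsets

    w, h = geometry.field_size_nm
    n_bg = n_a - n_partner
    b_bg = rng.uniform([0.0, 0.0], [w, h], size=(n_bg, 2))
    pos_b = np.clip(np.vstack([b_paired, b_bg]), [0.0, 0.0], [w, h])

    partner_a = np.full(n_a, -1, dtype=int)
    partner_a[partner_of] = np.arange(n_partner)
    partner_b = np.concatenate(
        [partner_of, np.full(n_bg, -1, dtype=int)]
    )
    mol_a = dataclasses.replace(mol_a, colocalized_partner=partner_a)
    mol_b = GroundTruthMolecules(
        positions_nm=pos_b,
        channel=channels[1],
        cluster_id=np.full(n_a, -1, dtype=int),
        colocalized_partner=partner_b,
    )
    return mol_a, mol_b


# ---------------------------------------------------------------------------
# SMLM rendering
# ---------------------------------------------------------------------------


def _integrated_gaussian_patch(
    x_nm: float,
    y_nm: float,
    sigma_nm: float,
    pixel_nm: float,
    cols: np.ndarray,
    rows: np.ndarray,
) -> np.ndarray:
    """PSF photon fractions integrated over the pixels (rows × cols).

    Pixel (i, j) spans [j*p, (j+1)*p) × [i*p, (i+1)*p) nm (half-open,
    origin at the field's top-left corner).
    """
    s = sigma_nm * np.sqrt(2.0)
    fx = 0.5 * (
        erf(((cols + 1) * pixel_nm - x_nm) / s) - erf((cols * pixel_nm - x_nm) / s)
    )
    fy = 0.5 * (
        erf(((rows + 1) * pixel_nm - y_nm) / s) - erf((rows * pixel_nm - y_nm) / s)
    )
    return fy[:, None] * fx[None, :]


def render_smlm_stack(
    molecules: GroundTruthMolecules,
    acq: AcquisitionParams,
    seed: int,
    field_size_nm: Sequence[float] | None = None,
    return_on_events: bool = False,
):
    """Render a blinking movie of ``molecules`` as a 16-bit stack.

    Each fluorophore is ON in each frame independently with probability
    ``acq.on_probability``; ON emitters contribute an integrated Gaussian
    PSF carrying ``photons_per_on_frame`` photons (Poisson shot noise when
    ``acq.shot_noise``), multiplied by the EM gain, plus Gaussian read
    noise and the camera baseline.  Values exceeding the bit depth are
    clipped; a warning reports the clipped-pixel count.

    Returns the stack (``uint16``, frames × rows × cols); when
    ``return_on_events`` also returns a boolean (n_frames, n_molecules)
    ON matrix (the ground-truth blink events).
    """
    rng = np.random.default_rng(seed)
    pos = molecules.positions_nm
    if field_size_nm is None:
        fw = float(pos[:, 0].max()) if pos.size else acq.pixel_nm
        fh = float(pos[:, 1].max()) if pos.size else acq.pixel_nm
    else:
        fw, fh = float(field_size_nm[0]), float(field_size_nm[1])
    n_cols = max(1, int(np.ceil(fw / acq.pixel_nm)))
    n_rows = max(1, int(np.ceil(fh / acq.pixel_nm)))
    if pos.size and (
        pos[:, 0].max() > n_cols * acq.pixel_nm or pos[:, 1].max() > n_rows * acq.pixel_nm
    ):
        raise ValueError("molecules fall outside the pixel grid")

    half = int(np.ceil(4 * acq.psf_sigma_nm / acq.pixel_nm))
    on = rng.uniform(size=(acq.n_frames, pos.shape[0])) < acq.on_probability

    max_adu = 2**acq.bit_depth - 1
    stack = np.empty((acq.n_frames, n_rows, n_cols), dtype=np.uint16)
    n_clipped = 0
    for f in range(acq.n_frames):
        photons = np.zeros((n_rows, n_cols))
        for m in np.flatnonzero(on[f]):
            x, y = pos[m]
            jc = int(x // acq.pixel_nm)
            ic = int(y // acq.pixel_nm)
            cols = np.arange(max(0, jc - half), min(n_cols, jc + half + 1))
            rows = np.arange(max(0, ic - half), min(n_rows, ic + half + 1))
            patch = _integrated_gaussian_patch(
                x, y, acq.psf_sigma_nm, acq.pixel_nm, cols, rows
            )
            photons[np.ix_(rows, cols)] += acq.photons_per_on_frame * patch
        if acq.shot_noise:
            photons = rng.poisson(photons).astype(float)
        frame = photons * acq.em_gain + acq.baseline_adu
        if acq.read_noise_adu > 0:
            frame = frame + rng.normal(0.0, acq.read_noise_adu, size=frame.shape)
        n_clipped += int((frame > max_adu).sum())
        stack[f] = np.clip(np.rint(frame), 0, max_adu).astype(np.uint16)
    if n_clipped:
        warnings.warn(f"{n_clipped} pixels clipped at {max_adu} ADU", stacklevel=2)
    if return_on_events:
        return stack, on
    return stack


# ---------------------------------------------------------------------------
# widefield rendering
# ---------------------------------------------------------------------------


def render_widefield_if(
    geometry: JunctionGeometry,
    belt_intensity: float,
    substrate: Substrate,
    n_slices: int = 10,
    seed: int = 0,
    pixel_nm: float = 320.0,
    focus_slice: int | None = None,
    noise: bool = True,
    belt_width_px: float = 1.0,
) -> np.ndarray:
    """Widefield immunofluorescence z-stack of the junction belt.

    One slice (``focus_slice``, default the middle) carries the sharp belt
    signal; slices further from focus carry increasingly Gaussian-blurred
    copies, emulating out-of-focus light.  A constant substrate-dependent
    background is added (glass < PC < PE) together with optional Poisson
    noise.  Returns a ``uint16`` array of shape (n_slices, rows, cols).
    """
    from scipy import ndimage
    from skimage.draw import line as draw_line

    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if substrate not in SUBSTRATE_BACKGROUND_ADU:
        raise ValueError(f"unknown substrate {substrate!r}")
    w, h = geometry.field_size_nm
    n_cols = max(1, int(np.ceil(w / pixel_nm)))
    n_rows = max(1, int(np.ceil(h / pixel_nm)))
    sharp = np.zeros((n_rows, n_cols))
    for belt in geometry.belts:
        px = np.clip((belt / pixel_nm).astype(int), 0, [n_cols - 1, n_rows - 1])
        for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            sharp[rr, cc] = 1.0
    if belt_width_px > 0:
        sharp = ndimage.gaussian_filter(sharp, belt_width_px)
        if sharp.max() > 0:
            sharp = sharp / sharp.max()
    sharp = belt_intensity * sharp

    focus = (n_slices - 1) // 2 if focus_slice is None else focus_slice
    bg = SUBSTRATE_BACKGROUND_ADU[substrate]
    rng = np.random.default_rng(seed)
    stack = np.empty((n_slices, n_rows, n_cols), dtype=np.uint16)
    for z in range(n_slices):
        dz = abs(z - focus)
        signal = sharp if dz == 0 else ndimage.gaussian_filter(sharp, 2.0 * dz)
        plane = signal + bg
        if noise:
            plane = rng.poisson(plane).astype(float)
        stack[z] = np.clip(np.rint(plane), 0, 2**16 - 1).astype(np.uint16)
    return stack


def belt_mask(
    geometry: JunctionGeometry,
    pixel_nm: float,
    halfwidth_nm: float = 0.0,
):
    """Rasterize the belt network into a binary ROI mask.

    Belt polylines are drawn onto the pixel grid and optionally dilated to
    ``halfwidth_nm`` on each side — the in-silico counterpart of manually
    annotating membrane areas on a widefield image.
    """
    from scipy import ndimage
    from skimage.draw import line as draw_line

    from .ifquant import ROIMask

    w, h = geometry.field_size_nm
    n_cols = max(1, int(np.ceil(w / pixel_nm)))
    n_rows = max(1, int(np.ceil(h / pixel_nm)))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for belt in geometry.belts:
        px = np.clip((belt / pixel_nm).astype(int), 0, [n_cols - 1, n_rows - 1])
        for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            mask[rr, cc] = True
    n_dilate = int(np.ceil(halfwidth_nm / pixel_nm))
    if n_dilate > 0:
        mask = ndimage.binary_dilation(mask, iterations=n_dilate)
    return ROIMask(mask=mask, pixel_nm=pixel_nm)


# ---------------------------------------------------------------------------
# functional (TER / flux) records
# ---------------------------------------------------------------------------


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size: int | tuple[int, ...]
) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=size)


def generate_functional_dataset(
    effects: EffectParams,
    n_replicates: int,
    seed: int,
    substrate: str = "PE",
    flux_control_conc_mg_ml: float = 0.05,
    calibration_slope_au_per_mg_ml: float = 2000.0,
    calibration_intercept_au: float = 5.0,
) -> FunctionalDataset:
    """TER trajectories, dextran-flux readings and calibration standards.

    Control TER trajectories are flat around ``baseline_ter_ohm_cm2``;
    treated trajectories are multiplied by ``ter_fold_1h`` / ``ter_fold_5h``
    at 1 h and 5 h.  Raw resistances include the substrate blank so
    downstream blank subtraction is exercised.  Basolateral fluorescence
    encodes dextran concentrations whose treated/control ratio has mean
    ``flux_fraction_of_control``; replicate noise is lognormal with mean 1
    and CV ``replicate_cv`` so that at ``replicate_cv=0`` the generator's
    parameters are recovered exactly.
    """
    if n_replicates < 3:
        raise ValueError("need at least 3 replicates")
    if substrate not in effects.blank_ohm:
        raise ValueError(f"no blank resistance configured for {substrate!r}")
    rng = np.random.default_rng(seed)
    blank = effects.blank_ohm[substrate]
    timepoints = (0.0, 1.0, 5.0)
    fold = {"control": {t: 1.0 for t in timepoints},
            "treated": {0.0: 1.0, 1.0: effects.ter_fold_1h, 5.0: effects.ter_fold_5h}}

    rows = []
    for condition in ("control", "treated"):
        base = effects.baseline_ter_ohm_cm2 * _lognormal_factor(
            rng, effects.replicate_cv, n_replicates
        )
        for t in timepoints:
            ter = base * fold[condition][t] * _lognormal_factor(
                rng, effects.replicate_cv, n_replicates
            ) if t > 0 else base
            raw = ter / effects.area_cm2 + blank
            for r in range(n_replicates):
                rows.append(
                    dict(condition=condition, replicate=r, timepoint_h=t,
                         raw_ohm=raw[r], blank_ohm=blank,
                         area_cm2=effects.area_cm2, substrate=substrate)
                )
    ter_df = pd.DataFrame(rows)

    conc = {
        "control": flux_control_conc_mg_ml
        * _lognormal_factor(rng, effects.replicate_cv, n_replicates),
        "treated": flux_control_conc_mg_ml
        * effects.flux_fraction_of_control
        * _lognormal_factor(rng, effects.replicate_cv, n_replicates),
    }
    flux_rows = []
    for condition, c in conc.items():
        au = calibration_slope_au_per_mg_ml * c + calibration_intercept_au
        for r in range(n_replicates):
            flux_rows.append(
                dict(condition=condition, replicate=r, compartment="basolateral",
                     timepoint_h=5.0, fluorescence_au=au[r])
            )
    flux_df = pd.DataFrame(flux_rows)

    std_conc = np.array([0.0, 0.025, 0.05, 0.1, 0.2])
    standards = pd.DataFrame(
        dict(
            conc_mg_ml=std_conc,
            fluorescence_au=calibration_slope_au_per_mg_ml * std_conc
            + calibration_intercept_au,
        )
    )
    return FunctionalDataset(ter=ter_df, flux=flux_df, standards=standards)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_ground_truth_csv(path: str | Path, *molecule_sets: GroundTruthMolecules) -> None:
    """Write ground-truth molecules as CSV (x_nm, y_nm, channel, cluster_id)."""
    frames = []
    for mol in molecule_sets:
        frames.append(
            pd.DataFrame(
                dict(
                    x_nm=mol.positions_nm[:, 0],
                    y_nm=mol.positions_nm[:, 1],
                    channel=mol.channel,
                    cluster_id=mol.cluster_id,
                )
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_parameter_sidecar(path: str | Path, **parameter_blocks) -> None:
    """Echo generation parameters to a JSON sidecar next to the data."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"cannot encode {type(obj)!r}")

    Path(path).write_text(json.dumps(parameter_blocks, default=encode, indent=2))
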