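"""Synthetic neck phantoms with ground-truth physiology.

A phantom is a 2D label map in the imaging plane (depth x lateral, probe at
depth 0) emulating an expert segmentation of the lateral neck: a coupling
stack (coupling medium, membrane, ultrasound gel) above dermis, subcutis and
bulk tissue, with a single elliptical lymph-node inclusion embedded in the
bulk.  Each class carries a chromophore composition and acoustic properties
from an editable table; voxel-wise optical absorption follows the linear
mixing rule

    mua(lambda) = BVF * [sO2 * mua_HbO2 + (1 - sO2) * mua_Hb]
                  + W * mua_water + F * mua_fat + M * mua_melanin

and reduced scattering the power law mus'(lambda) = a * (lambda/500 nm)^-b.

Lymph nodes are assigned a ground-truth (BVF, sO2) drawn from one of three
clinically informed disease states: malignant (BVF 4 +/- 2 %, sO2 43 +/- 15 %),
benign (14 +/- 7 %, 73 +/- 15 %) and an artificial intermediate state
(9 +/- 4.5 %, 58 +/- 15 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage, stats

from .spectra import ChromophoreSpectra, default_spectra

__all__ = [
    "CLASS_NAMES",
    "MATERIAL_CLASSES",
    "TISSUE_CLASSES",
    "DiseaseState",
    "DISEASE_STATES",
    "NodeGroundTruth",
    "LabelMap",
    "GeometryConfig",
    "TissueProperties",
    "PropertyTable",
    "TissuePhantom",
    "PhantomGenerationError",
    "sample_node_properties",
    "generate_label_map",
    "compute_absorption",
    "build_phantom",
    "default_property_table",
    "clipped_normal_mean",
]

#: Fixed label ids, ordered along depth for the layer classes.
CLASS_NAMES = {
    0: "coupling_medium",
    1: "membrane",
    2: "ultrasound_gel",
    3: "dermis",
    4: "subcutis",
    5: "bulk_tissue",
    6: "lymph_node",
}
MATERIAL_CLASSES = ("coupling_medium", "membrane", "ultrasound_gel")
TISSUE_CLASSES = ("dermis", "subcutis", "bulk_tissue", "lymph_node")
_NAME_TO_LABEL = {v: k for k, v in CLASS_NAMES.items()}


class PhantomGenerationError(RuntimeError):
    """Raised when a valid phantom cannot be generated from a configuration."""


# ---------------------------------------------------------------------------
# disease states and node ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseState:
    """Gaussian (BVF, sO2) distribution characterising a lymph-node state."""

    name: str
    bvf_mean: float
    bvf_sd: float
    so2_mean: float
    so2_sd: float

    def __post_init__(self):
        if not (0.0 <= self.bvf_mean <= 1.0 and 0.0 <= self.so2_mean <= 1.0):
            raise ValueError("disease-state means must lie in [0, 1]")
        if self.bvf_sd < 0 or self.so2_sd < 0:
            raise ValueError("disease-state standard deviations must be >= 0")


#: The three built-in node states (fractions, not percent).
DISEASE_STATES = {
    "malignant": DiseaseState("malignant", 0.04, 0.02, 0.43, 0.15),
    "benign": DiseaseState("benign", 0.14, 0.07, 0.73, 0.15),
    "intermediate": DiseaseState("intermediate", 0.09, 0.045, 0.58, 0.15),
}

#: Lower clip bound for sampled BVF (a node with exactly zero blood would
#: carry no hemoglobin signal at all and has no defined sO2).
BVF_FLOOR = 1e-3


@dataclass(frozen=True)
class NodeGroundTruth:
    """Ground-truth physiology assigned to one lymph-node instance."""

    bvf: float
    so2: float
    state_name: str = ""

    def __post_init__(self):
        if not (0.0 <= self.bvf <= 1.0 and 0.0 <= self.so2 <= 1.0):
            raise ValueError("node ground truth must lie in [0, 1]")


def sample_node_properties(state: DiseaseState | str, rng_seed) -> NodeGroundTruth:
    """Draw one (BVF, sO2) ground truth from a disease state.

    Draws are Gaussian with the state's mean and sd, clipped to
    [``BVF_FLOOR``, 1] for BVF and [0, 1] for sO2.  ``rng_seed`` may be an
    integer seed or a ``numpy.random.Generator``.
    """
    if isinstance(state, str):
        try:
            state = DISEASE_STATES[state]
        except KeyError:
            raise ValueError(
                f"unknown disease state {state!r}; expected one of "
                f"{sorted(DISEASE_STATES)}"
            ) from None
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    bvf = float(np.clip(rng.normal(state.bvf_mean, state.bvf_sd), BVF_FLOOR, 1.0))
    so2 = float(np.clip(rng.normal(state.so2_mean, state.so2_sd), 0.0, 1.0))
    return NodeGroundTruth(bvf=bvf, so2=so2, state_name=state.name)


def clipped_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Exact mean of clip(Normal(mean, sd), lo, hi).

    Closed form used as the reference against which sample means of disease
    -state draws are judged (the clipping introduces a small bias relative to
    the nominal mean).
    """
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    return float(lo * Fa + hi * (1 - Fb) + mean * (Fb - Fa) - sd * (fb - fa))


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

@dataclass
class LabelMap:
    """Semantic segmentation of the imaging plane.

    ``labels`` has shape (depth, lateral); depth index 0 touches the probe.
    """

    labels: np.ndarray
    spacing: float  # mm per voxel (isotropic)
    class_table: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D (depth x lateral) grid")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, class_name: str) -> np.ndarray:
        label = _NAME_TO_LABEL[class_name]
        return self.labels == label

    def present_classes(self) -> set[str]:
        return {self.class_table[int(v)] for v in np.unique(self.labels)}

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        for v in np.unique(self.labels):
            if int(v) not in self.class_table:
                raise ValueError(f"label {int(v)} missing from class table")
        node = self.mask("lymph_node")
        if node.any():
            n_comp = ndimage.label(node)[1]
            if n_comp != 1:
                raise ValueError("lymph node must be a single connected component")
            # every node-adjacent voxel outside the node must be bulk tissue
            ring = ndimage.binary_dilation(node) & ~node
            if not np.all(self.labels[ring] == _NAME_TO_LABEL["bulk_tissue"]):
                raise ValueError("lymph node must lie fully inside bulk tissue")
        # layers ordered along depth: per column, first occurrences increase
        order = [_NAME_TO_LABEL[c] for c in
                 ("coupling_medium", "membrane", "ultrasound_gel",
                  "dermis", "subcutis", "bulk_tissue")]
        for col in self.labels.T:
            firsts = [np.argmax(col == lab) for lab in order if (col == lab).any()]
            if firsts != sorted(firsts):
                raise ValueError("layer classes out of depth order")


@dataclass(frozen=True)
class GeometryConfig:
    """Randomized-geometry ranges for :func:`generate_label_map`.

    Thicknesses and the node depth are in mm; the node depth is measured
    from the tissue surface (top of dermis) to the node centre.
    """

    shape: tuple[int, int] = (256, 128)
    spacing: float = 0.1
    coupling_thickness: float = 2.0
    membrane_thickness: float = 0.2
    gel_thickness: float = 0.5
    dermis_range: tuple[float, float] = (1.5, 2.5)
    subcutis_range: tuple[float, float] = (2.0, 5.0)
    node_depth_range: tuple[float, float] = (8.0, 14.0)
    node_radius_range: tuple[float, float] = (2.0, 5.0)
    boundary_wobble: float = 0.3  # amplitude (mm) of layer-boundary undulation


def generate_label_map(geometry: GeometryConfig | None = None,
                       rng_seed=0) -> LabelMap:
    """Generate a randomized layered neck label map with one node inclusion.

    Layer thicknesses are drawn uniformly from the configured ranges, layer
    boundaries get a gentle sinusoidal undulation, and a single elliptical
    lymph node is placed fully inside the bulk tissue.  A configuration whose
    node cannot fit raises :class:`PhantomGenerationError`.  Setting the node
    radius range to (0, 0) produces a phantom without a node.
    """
    geom = geometry or GeometryConfig()
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    nz, nx = geom.shape
    dz = geom.spacing
    labels = np.full((nz, nx), _NAME_TO_LABEL["bulk_tissue"], dtype=np.uint8)

    x = np.arange(nx)
    def wobble():
        phase = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(0.5, 1.5) * nx
        return geom.boundary_wobble * np.sin(2 * np.pi * x / period + phase)

    # interfaces (mm, per column); the coupling stack is kept flat
    z_membrane = np.full(nx, geom.coupling_thickness)
    z_gel = z_membrane + geom.membrane_thickness
    z_dermis = z_gel + geom.gel_thickness
    dermis_t = rng.uniform(*geom.dermis_range)
    subcutis_t = rng.uniform(*geom.subcutis_range)
    z_subcutis = z_dermis + dermis_t + wobble()
    z_bulk = z_subcutis + subcutis_t + wobble()

    zc = (np.arange(nz)[:, None] + 0.5) * dz  # voxel-centre depth (mm)
    labels[zc < z_bulk] = _NAME_TO_LABEL["subcutis"]
    labels[zc < z_subcutis] = _NAME_TO_LABEL["dermis"]
    labels[zc < z_dermis[None, :]] = _NAME_TO_LABEL["ultrasound_gel"]
    labels[zc < z_gel[None, :]] = _NAME_TO_LABEL["membrane"]
    labels[zc < z_membrane[None, :]] = _NAME_TO_LABEL["coupling_medium"]

    r_lo, r_hi = geom.node_radius_range
    if r_hi > 0:
        surface = float(z_dermis.mean())
        bulk_top = float(z_bulk.max())
        placed = False
        for _ in range(50):
            rz = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            depth = rng.uniform(*geom.node_depth_range)
            cz = surface + depth
            margin = dz  # one voxel of bulk must separate node from neighbours
            if cz - rz <= bulk_top + margin or cz + rz >= nz * dz - margin:
                continue
            if 2 * rx >= nx * dz - 4 * margin:
                continue
            cx = rng.uniform(rx + 2 * margin, nx * dz - rx - 2 * margin)
            xc = (np.arange(nx)[None, :] + 0.5) * dz
            ellipse = ((zc - cz) / rz) ** 2 + ((xc - cx) / rx) ** 2 <= 1.0
            if not ellipse.any():
                continue
            if np.all(labels[ellipse] == _NAME_TO_LABEL["bulk_tissue"]):
                labels[ellipse] = _NAME_TO_LABEL["lymph_node"]
                placed = True
                break
        if not placed:
            raise PhantomGenerationError(
                "could not place a lymph node inside bulk tissue for the "
                "given geometry ranges"
            )
    return LabelMap(labels=labels, spacing=dz)


# ---------------------------------------------------------------------------
# properties and absorption
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProperties:
    """Composition plus optical/acoustic constants for one class."""

    blood_volume_fraction: float = 0.0
    so2: float = 0.0
    water_fraction: float = 0.0
    fat_fraction: float = 0.0
    melanin_fraction: float = 0.0
    mus500: float = 0.0          # reduced scattering at 500 nm (per mm)
    scattering_power: float = 1.0
    gruneisen: float = 0.0
    speed_of_sound: float = 1.5  # mm / us
    density: float = 1000.0      # kg / m^3
    acoustic_attenuation: float = 0.0  # dB / MHz / cm

    def __post_init__(self):
        for name in ("blood_volume_fraction", "so2", "water_fraction",
                     "fat_fraction", "melanin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.speed_of_sound <= 0 or self.density <= 0 or self.mus500 < 0:
            raise ValueError("acoustic/scattering constants out of range")


PropertyTable = dict  # class name -> TissueProperties


def default_property_table() -> PropertyTable:
    """Load the editable default property table shipped with the package."""
    path = resources.files("paitwin.data") / "tissue_properties.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return {name: TissueProperties(**vals) for name, vals in raw.items()}


def compute_absorption(composition, spectra: ChromophoreSpectra,
                       wavelength: float, background: float = 0.0):
    """Voxel absorption coefficient (per mm) from a chromophore composition.

    ``composition`` is anything exposing ``blood_volume_fraction``, ``so2``,
    ``water_fraction``, ``fat_fraction`` and ``melanin_fraction`` attributes
    (scalars or broadcastable arrays).  ``background`` adds a constant
    baseline absorption (default 0).  The result is exactly linear in each
    fraction.
    """
    if background < 0:
        raise ValueError("background absorption must be >= 0")
    bvf = np.asarray(composition.blood_volume_fraction, dtype=float)
    so2 = np.asarray(composition.so2, dtype=float)
    mua = (
        bvf * spectra.blood_absorption(so2, wavelength)
        + np.asarray(composition.water_fraction, dtype=float)
        * spectra.absorption("water", wavelength)
        + np.asarray(composition.fat_fraction, dtype=float)
        * spectra.absorption("fat", wavelength)
        + np.asarray(composition.melanin_fraction, dtype=float)
        * spectra.absorption("melanin", wavelength)
        + background
    )
    return float(mua) if mua.ndim == 0 else mua


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

@dataclass
class TissuePhantom:
    """Label map plus per-voxel, per-wavelength property grids.

    ``mua`` and ``mus_reduced`` have shape (n_wavelengths, depth, lateral);
    the acoustic grids and the ground-truth maps share the label-map shape.
    """

    label_map: LabelMap
    wavelengths: np.ndarray
    mua: np.ndarray
    mus_reduced: np.ndarray
    gruneisen: np.ndarray
    sos: np.ndarray
    density: np.ndarray
    attenuation: np.ndarray
    so2_truth: np.ndarray
    bvf_truth: np.ndarray
    node_truth: NodeGroundTruth | None = None

    @property
    def spacing(self) -> float:
        return self.label_map.spacing

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def wavelength_index(self, wavelength: float) -> int:
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not in phantom")
        return int(idx[0])

    def node_mask(self) -> np.ndarray:
        return self.label_map.mask("lymph_node")


def build_phantom(label_map: LabelMap,
                  property_table: PropertyTable | None = None,
                  node_truth: NodeGroundTruth | None = None,
                  wavelengths=None,
                  spectra: ChromophoreSpectra | None = None,
                  background: float = 0.0,
                  bvf_heterogeneity: float = 0.3,
                  texture_seed=0) -> TissuePhantom:
    """Populate property grids from a label map and a property table.

    Lymph-node voxels take their blood volume fraction and oxygenation from
    ``node_truth`` (required when the map contains a node); every other class
    uses the table composition as-is.

    ``bvf_heterogeneity`` adds multiplicative composition texture (relative
    sd, mean-preserving per class region) to the chromophore fractions,
    emulating the granular character of real tissue: blood resides in
    discrete microvessels and the other constituents are not perfectly
    homogeneous either.  One shared random field (cell size ~0.2 mm)
    multiplies the blood, water, fat and melanin fractions, so a voxel's
    *relative* composition — in particular its sO2 — is untouched and the
    region-mean of every fraction stays exact; the node ground truth is
    preserved.  Set it to 0 for perfectly homogeneous regions.
    """
    table = property_table if property_table is not None else default_property_table()
    spectra = spectra or default_spectra()
    wl = np.asarray(
        wavelengths if wavelengths is not None else ACQUISITION_WAVELENGTHS,
        dtype=float,
    )
    present = label_map.present_classes()
    missing = present - set(table)
    if missing:
        raise KeyError(f"property table missing classes: {sorted(missing)}")
    if "lymph_node" in present and node_truth is None:
        raise ValueError("label map contains a lymph node but no node_truth given")
    if bvf_heterogeneity < 0:
        raise ValueError("bvf_heterogeneity must be >= 0")

    nz, nx = label_map.shape
    labels = label_map.labels
    grun = np.zeros((nz, nx))
    sos = np.zeros((nz, nx))
    dens = np.zeros((nz, nx))
    att = np.zeros((nz, nx))
    so2_map = np.zeros((nz, nx))
    bvf_map = np.zeros((nz, nx))
    water = np.zeros((nz, nx))
    fat = np.zeros((nz, nx))
    melanin = np.zeros((nz, nx))
    mus500 = np.zeros((nz, nx))
    spower = np.ones((nz, nx))

    rng = np.random.default_rng(texture_seed) if not isinstance(
        texture_seed, np.random.Generator) else texture_seed
    # white random field with a fixed physical cell size (~0.2 mm, the scale
    # of the microvasculature) so the texture statistics do not depend on
    # the voxel size
    cell = max(1, int(round(0.2 / label_map.spacing)))
    coarse = rng.standard_normal((-(-nz // cell), -(-nx // cell)))
    field = np.repeat(np.repeat(coarse, cell, axis=0), cell, axis=1)[:nz, :nx]
    # floor keeps every tissue voxel weakly perfused/absorbing
    texture = np.maximum(1.0 + bvf_heterogeneity * field, 0.05)

    for label, name in label_map.class_table.items():
        mask = labels == label
        if not mask.any():
            continue
        props = table[name]
        if name == "lymph_node":
            props = replace(props, blood_volume_fraction=node_truth.bvf,
                            so2=node_truth.so2)
        grun[mask] = props.gruneisen
        sos[mask] = props.speed_of_sound
        dens[mask] = props.density
        att[mask] = props.acoustic_attenuation
        so2_map[mask] = props.so2
        mus500[mask] = props.mus500
        spower[mask] = props.scattering_power
        if bvf_heterogeneity > 0 and name not in MATERIAL_CLASSES:
            tex = texture[mask]
            tex = tex / tex.mean()  # region means stay exact
        else:
            tex = 1.0
        bvf_map[mask] = np.minimum(props.blood_volume_fraction * tex, 1.0)
        water[mask] = np.minimum(props.water_fraction * tex, 1.0)
        fat[mask] = np.minimum(props.fat_fraction * tex, 1.0)
        melanin[mask] = np.minimum(props.melanin_fraction * tex, 1.0)

    class _VoxelComposition:
        blood_volume_fraction = bvf_map
        so2 = so2_map
        water_fraction = water
        fat_fraction = fat
        melanin_fraction = melanin

    mua = np.stack([
        compute_absorption(_VoxelComposition, spectra, lam, background)
        for lam in wl
    ])
    mus = np.stack([mus500 * (lam / 500.0) ** (-spower) for lam in wl])

    return TissuePhantom(
        label_map=label_map, wavelengths=wl, mua=mua, mus_reduced=mus,
        gruneisen=grun, sos=sos, density=dens, attenuation=att,
        so2_truth=so2_map, bvf_truth=bvf_map, node_truth=node_truth,
    )


#: The device acquisition wavelengths (nm).
ACQUISITION_WAVELENGTHS = (680, 700, 730, 760, 800, 850, 920, 1000, 1030, 1064, 1100)
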