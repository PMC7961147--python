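"""Synthetic single-cell morphology, YAP/TAZ, and scaffold-mechanics data.

Cells grown on engineered fiber networks adopt heterogeneous shapes; their
mechanosensitive state (nuclear/cytoplasmic YAP/TAZ) tracks morphology unless
a biochemical cue or a phenotype switch decouples the two.  This module
emulates that situation: it draws cell/nucleus shape descriptors from a small
set of morphologic archetypes, maps morphology to a YAP/TAZ ratio through a
smooth saturating coupling with controlled noise, applies additive
contractility-cue shifts and planted decoupling offsets, renders label masks
for end-to-end morphometry tests, and forward-simulates stress-strain curves
from the fiber-network constitutive model.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mechanics

#: The 14 shape descriptors, in canonical table order.
FEATURE_COLUMNS = [
    "cell_area_um2",
    "cell_perimeter_um",
    "cell_major_um",
    "cell_minor_um",
    "cell_bound_len_um",
    "cell_bound_wid_um",
    "cell_aspect",
    "cell_solidity",
    "cell_roundness",
    "cell_circularity",
    "cell_angle_deg",
    "nuc_area_um2",
    "nuc_aspect",
    "nuc_angle_deg",
]

#: Canonical CSV schema for cell tables.
TABLE_COLUMNS = ["cell_id", "group", "cue", "decoupled", *FEATURE_COLUMNS, "yap_ratio"]

#: Positive floor applied to generated YAP/TAZ ratios (a nuclear/cytoplasmic
#: ratio is positive by definition).
YAP_FLOOR = 0.1


@dataclass(frozen=True)
class ArchetypeSpec:
    """One morphologic archetype: descriptor ranges for a shape group.

    ``area_range`` is in um^2, ``angle_spread`` in degrees (cells orient
    uniformly within +/- spread of the reference axis), ``nucleus_scale`` is
    the nuclear/cell area fraction, and ``lobes`` counts sinusoidal boundary
    protrusions used when rasterizing.
    """

    name: str
    area_range: tuple[float, float]
    aspect_ratio_range: tuple[float, float]
    angle_spread: float
    solidity_range: tuple[float, float]
    nucleus_scale: float
    lobes: int = 0

    def __post_init__(self) -> None:
        for rng_name in ("area_range", "aspect_ratio_range", "solidity_range"):
            lo, hi = getattr(self, rng_name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi < lo:
                raise ValueError(f"{self.name}: invalid {rng_name} ({lo}, {hi})")
        if self.aspect_ratio_range[0] < 1:
            raise ValueError(f"{self.name}: aspect ratio must be >= 1")
        if not (0 < self.solidity_range[0] <= self.solidity_range[1] <= 1):
            raise ValueError(f"{self.name}: solidity must lie in (0, 1]")
        if not (0 < self.nucleus_scale < 1):
            raise ValueError(f"{self.name}: nucleus_scale must lie in (0, 1)")
        if self.angle_spread < 0 or not np.isfinite(self.angle_spread):
            raise ValueError(f"{self.name}: angle_spread must be finite and >= 0")
        if self.lobes < 0:
            raise ValueError(f"{self.name}: lobes must be >= 0")


# Four default archetypes mirroring the qualitative shape groups seen on
# strained fiber networks: (1) off-axis spreading with low solidity and low
# aspect ratio, (2) very large spread cells with low circularity, (3) round
# compact cells with round nuclei, (4) small, highly elongated, on-axis cells.
DEFAULT_ARCHETYPES: list[ArchetypeSpec] = [
    ArchetypeSpec("off_axis", (1500.0, 3500.0), (1.0, 1.6), 60.0, (0.45, 0.65), 0.16, 5),
    ArchetypeSpec("large_spread", (4000.0, 7000.0), (1.4, 2.4), 30.0, (0.60, 0.80), 0.10, 4),
    ArchetypeSpec("round", (1200.0, 2600.0), (1.0, 1.25), 90.0, (0.85, 0.97), 0.22, 0),
    ArchetypeSpec("small_elongated", (500.0, 1200.0), (3.0, 6.0), 10.0, (0.75, 0.92), 0.25, 0),
]


@dataclass(frozen=True)
class CouplingSpec:
    """Morphology -> YAP/TAZ coupling.

    yap = baseline + sum_j coefficients[j] * tanh((x_j - midpoint_j)/scale_j)
          + cue_shifts[cue] + decouple_offset * [decoupled] + N(0, noise_sd),
    clipped to ``YAP_FLOOR``.

    Defaults: the coupling is dominated by cell aspect ratio, cell area, and
    nuclear area (the most predictive descriptors); cue shifts reproduce the
    measured contractility-drug displacements (-0.60 for the ROCK inhibitor,
    +0.69 for the RhoA agonist); the decoupling offset defaults to the
    invasive-cell calibration (mean 1.52, SD 0.88).
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "cell_aspect": 0.45,
            "cell_area_um2": 0.35,
            "nuc_area_um2": 0.25,
        }
    )
    midpoints: dict[str, float] = field(
        default_factory=lambda: {
            "cell_aspect": 2.2,
            "cell_area_um2": 2600.0,
            "nuc_area_um2": 420.0,
        }
    )
    scales: dict[str, float] = field(
        default_factory=lambda: {
            "cell_aspect": 1.3,
            "cell_area_um2": 1600.0,
            "nuc_area_um2": 260.0,
        }
    )
    baseline: float = 1.3
    noise_sd: float = 0.35
    cue_shifts: dict[int, float] = field(
        default_factory=lambda: {-1: -0.60, 0: 0.0, 1: 0.69}
    )
    decouple_offset_mean: float = 1.52
    decouple_offset_sd: float = 0.88

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cue_shifts.get(0, None) != 0.0:
            raise ValueError("cue_shifts[0] must be 0 (control medium)")
        if set(self.coefficients) - set(self.midpoints) or set(self.coefficients) - set(
            self.scales
        ):
            raise ValueError("every coupled descriptor needs a midpoint and scale")


def _ellipse_perimeter(major: np.ndarray, minor: np.ndarray) -> np.ndarray:
    # Ramanujan's second approximation on semi-axes.
    a, b = np.asarray(major) / 2.0, np.asarray(minor) / 2.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def generate_population(
    archetypes: list[ArchetypeSpec] | None = None,
    n_per_archetype: int = 261,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a morphology-only cell table from the given archetypes.

    Returns ``n_per_archetype * len(archetypes)`` records.  Sampled
    descriptors (area, aspect ratio, solidity, angle) are uniform within the
    archetype ranges; the remaining descriptors are deterministic geometric
    consequences (ellipse relations), so zero-width ranges give identical
    records.
    """
    if archetypes is None:
        archetypes = DEFAULT_ARCHETYPES
    if len(archetypes) == 0:
        raise ValueError("archetype list is empty")
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for arch in archetypes:
        n = n_per_archetype
        area = rng.uniform(*arch.area_range, size=n)
        aspect = rng.uniform(*arch.aspect_ratio_range, size=n)
        solidity = rng.uniform(*arch.solidity_range, size=n)
        spread = min(arch.angle_spread, 90.0)
        if spread == 0:
            angle = np.zeros(n)
        else:
            angle = rng.uniform(-spread, spread, size=n)
        angle = np.clip(angle, -90.0, np.nextafter(90.0, 0.0))

        major = np.sqrt(4.0 * area * aspect / math.pi)
        minor = major / aspect
        perimeter = _ellipse_perimeter(major, minor) / solidity**0.75
        circularity = np.clip(4 * math.pi * area / perimeter**2, None, 1.0)
        roundness = 1.0 / aspect
        rad = np.radians(angle)
        bound_len = np.sqrt((major * np.cos(rad)) ** 2 + (minor * np.sin(rad)) ** 2)
        bound_wid = np.sqrt((major * np.sin(rad)) ** 2 + (minor * np.cos(rad)) ** 2)
        nuc_area = arch.nucleus_scale * area
        nuc_aspect = 1.0 + 0.45 * (aspect - 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "group": arch.name,
                    "cue": 0,
                    "decoupled": False,
                    "cell_area_um2": area,
                    "cell_perimeter_um": perimeter,
                    "cell_major_um": major,
                    "cell_minor_um": minor,
                    "cell_bound_len_um": bound_len,
                    "cell_bound_wid_um": bound_wid,
                    "cell_aspect": aspect,
                    "cell_solidity": solidity,
                    "cell_roundness": roundness,
                    "cell_circularity": circularity,
                    "cell_angle_deg": angle,
                    "nuc_area_um2": nuc_area,
                    "nuc_aspect": nuc_aspect,
                    "nuc_angle_deg": angle,
                    "lobes": arch.lobes,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(table))])
    return table


def archetype_separation(table: pd.DataFrame) -> float:
    """Minimum pairwise centroid distance between groups in z-scored space."""
    feats = table[FEATURE_COLUMNS].to_numpy(float)
    z = (feats - feats.mean(0)) / np.where(feats.std(0) > 0, feats.std(0), 1.0)
    centroids = [z[(table["group"] == g).to_numpy()].mean(0) for g in table["group"].unique()]
    dmin = np.inf
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            dmin = min(dmin, float(np.linalg.norm(centroids[i] - centroids[j])))
    return dmin


# ---------------------------------------------------------------------------
# Mask rendering
# ---------------------------------------------------------------------------

def _superellipse_boundary(
    record, pixel_size: float, lobes: int, lobe_amp: float, phase: float, n_vertices: int = 720
):
    """Boundary vertices (x, y-up; um) of a lobed ellipse matching the record."""
    area = float(record["cell_area_um2"])
    aspect = float(record["cell_aspect"])
    angle = math.radians(float(record["cell_angle_deg"]))
    major = math.sqrt(4.0 * area * aspect / math.pi)
    a, b = major / 2.0, major / (2.0 * aspect)
    t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    m = 1.0 + lobe_amp * np.cos(lobes * t + phase) if lobes > 0 else np.ones_like(t)
    # Boundary modulation scales the enclosed area by (1 + amp^2/2); undo it.
    if lobes > 0:
        s = 1.0 / math.sqrt(1.0 + lobe_amp**2 / 2.0)
        a, b = a * s, b * s
    x, y = m * a * np.cos(t), m * b * np.sin(t)
    c, s_ = math.cos(angle), math.sin(angle)
    return x * c - y * s_, x * s_ + y * c


def render_cell_mask(
    record,
    pixel_size: float = 1.0,
    canvas: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a cell record into (cell mask, nucleus mask) label images.

    The cell is a rotated ellipse with optional sinusoidal lobes (amplitude
    tied to 1 - solidity); the nucleus is a concentric ellipse with the
    record's nuclear area and aspect ratio, shrunk if needed so it lies
    strictly inside the cell.  Masks are uint16 with label 1.
    """
    from skimage.draw import polygon

    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    lobes = int(record.get("lobes", 0) if hasattr(record, "get") else getattr(record, "lobes", 0))
    solidity = float(record["cell_solidity"])
    lobe_amp = float(np.clip(0.9 * (1.0 - solidity), 0.0, 0.45)) if lobes > 0 else 0.0
    phase = float(rng.uniform(0, 2 * math.pi))

    h, w = canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    bx, by = _superellipse_boundary(record, pixel_size, lobes, lobe_amp, phase)
    cols = cx + bx / pixel_size
    rows = cy - by / pixel_size
    if cols.min() < 1 or rows.min() < 1 or cols.max() > w - 2 or rows.max() > h - 2:
        raise ValueError("shape exceeds canvas; enlarge canvas or raise pixel_size")
    cell = np.zeros(canvas, dtype=np.uint16)
    rr, cc = polygon(rows, cols, shape=canvas)
    cell[rr, cc] = 1

    nuc_area = float(record["nuc_area_um2"])
    nuc_aspect = float(record["nuc_aspect"])
    nuc_angle = math.radians(float(record["nuc_angle_deg"]))
    n_major = math.sqrt(4.0 * nuc_area * nuc_aspect / math.pi)
    na, nb = n_major / 2.0, n_major / (2.0 * nuc_aspect)
    t = np.linspace(0, 2 * math.pi, 360, endpoint=False)
    for shrink_try in range(40):
        f = 0.97**shrink_try
        x, y = f * na * np.cos(t), f * nb * np.sin(t)
        c_, s_ = math.cos(nuc_angle), math.sin(nuc_angle)
        ncols = cx + (x * c_ - y * s_) / pixel_size
        nrows = cy - (x * s_ + y * c_) / pixel_size
        nuc = np.zeros(canvas, dtype=np.uint16)
        rr, cc = polygon(nrows, ncols, shape=canvas)
        nuc[rr, cc] = 1
        if nuc.sum() > 0 and np.all(cell[nuc > 0] == 1):
            return cell, nuc
    raise ValueError("could not fit nucleus strictly inside the cell mask")


# ---------------------------------------------------------------------------
# YAP assignment
# ---------------------------------------------------------------------------

def deterministic_yap(records: pd.DataFrame, coupling: CouplingSpec) -> np.ndarray:
    """Noise-free morphology-driven component of the YAP ratio (no cue/offset)."""
    y = np.full(len(records), coupling.baseline, dtype=float)
    for name, coef in coupling.coefficients.items():
        x = records[name].to_numpy(float)
        y += coef * np.tanh((x - coupling.midpoints[name]) / coupling.scales[name])
    return y


def noise_sd_for_explainable_variance(
    records: pd.DataFrame, coupling: CouplingSpec, target_ev: float
) -> float:
    """Noise SD such that var(deterministic)/var(total) equals ``target_ev``."""
    if not (0 < target_ev <= 1):
        raise ValueError("target_ev must lie in (0, 1]")
    var_det = float(np.var(deterministic_yap(records, coupling)))
    return math.sqrt(var_det * (1.0 / target_ev - 1.0))


def assign_yap(
    records: pd.DataFrame,
    coupling: CouplingSpec | None = None,
    cue=None,
    decoupled=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Attach a ``yap_ratio`` column; returns (table copy, ground-truth info).

    ``cue`` is a per-record value in {-1, 0, +1} (scalar broadcastable);
    ``decoupled`` a per-record boolean.  The info dict reports the empirical
    explainable variance var(det)/(var(det)+noise_sd^2) of the coupled,
    control-cue portion before clipping.
    """
    coupling = coupling or CouplingSpec()
    rng = np.random.default_rng(seed)
    n = len(records)
    cue_arr = np.broadcast_to(np.asarray(0 if cue is None else cue), (n,)).astype(int)
    if not np.isin(cue_arr, (-1, 0, 1)).all():
        raise ValueError("cue values must be in {-1, 0, +1}")
    dec_arr = np.broadcast_to(
        np.asarray(False if decoupled is None else decoupled), (n,)
    ).astype(bool)

    det = deterministic_yap(records, coupling)
    shifts = np.array([coupling.cue_shifts[int(c)] for c in cue_arr])
    offsets = np.where(
        dec_arr,
        rng.normal(coupling.decouple_offset_mean, coupling.decouple_offset_sd, size=n),
        0.0,
    )
    noise = rng.normal(0.0, coupling.noise_sd, size=n) if coupling.noise_sd > 0 else 0.0
    yap = np.maximum(det + shifts + offsets + noise, YAP_FLOOR)

    out = records.copy()
    out["cue"] = cue_arr
    out["decoupled"] = dec_arr
    out["yap_ratio"] = yap
    var_det = float(np.var(det))
    info = {
        "var_deterministic": var_det,
        "noise_sd": coupling.noise_sd,
        "explainable_variance": var_det / (var_det + coupling.noise_sd**2)
        if var_det + coupling.noise_sd**2 > 0
        else 0.0,
    }
    return out, info


# ---------------------------------------------------------------------------
# Mechanics curves
# ---------------------------------------------------------------------------

def generate_stress_strain(
    params: "mechanics.FiberModelParams",
    strain_max: float = 0.09,
    n_points: int = 46,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulate a stress-strain table with multiplicative noise."""
    if strain_max <= 0:
        raise ValueError("strain_max must be > 0")
    strain = np.linspace(0.0, strain_max, n_points)
    curve = mechanics.predict_stress(strain, params)
    stress = curve.stress_mpa.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + rng.normal(0.0, noise_cv, size=stress.shape))
        stress[strain == 0] = 0.0
    return pd.DataFrame({"strain": strain, "stress_mpa": stress})


def generate_angle_histograms(
    params: "mechanics.FiberModelParams",
    strains=(0.0, 0.03, 0.06, 0.09),
    n_bins: int = 60,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list["mechanics.AngleHistogram"]:
    """Fiber-angle histograms drawn from the strain-dependent Gaussian model."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = []
    for eps in strains:
        dens = mechanics.angle_distribution(centers, eps, params)
        if noise_cv > 0:
            dens = dens * (1.0 + rng.normal(0.0, noise_cv, size=dens.shape))
            dens = np.clip(dens, 0.0, None)
        dens = dens / np.trapezoid(dens, centers)
        out.append(mechanics.AngleHistogram(centers, dens, float(eps)))
    return out


# ---------------------------------------------------------------------------
# Invasiveness study condition
# ---------------------------------------------------------------------------

# Two-class condition: the non-invasive class draws from epithelial-like
# archetypes; the invasive class is a morphologic mixture — half drawn from
# the same epithelial archetypes (indistinguishable by shape) and half from
# an elongated mesenchymal archetype — and every invasive cell carries the
# YAP decoupling offset.  Morphology alone therefore misses the shared-shape
# half, YAP alone separates better, and the combination is best; removing the
# offset ("stiff 2D") collapses the YAP-only classifier toward chance.
NONINVASIVE_ARCHETYPES = [
    ArchetypeSpec("epithelial_round", (900.0, 3200.0), (1.0, 2.4), 60.0, (0.68, 0.95), 0.20, 0),
    ArchetypeSpec("epithelial_spread", (1400.0, 4000.0), (1.2, 2.8), 60.0, (0.60, 0.90), 0.16, 3),
]
INVASIVE_ARCHETYPES = [
    ArchetypeSpec("mesenchymal_elong", (600.0, 2600.0), (2.5, 5.0), 60.0, (0.50, 0.78), 0.22, 3),
]
#: Fraction of invasive cells drawn from the shared epithelial archetypes.
INVASIVE_SHARED_FRACTION = 0.5


def generate_invasiveness_dataset(
    n_per_class: int = 150,
    seed: int = 0,
    decouple: bool = True,
    coupling: CouplingSpec | None = None,
) -> pd.DataFrame:
    """Two-class cell table with an ``invasive`` boolean label column."""
    coupling = coupling or CouplingSpec()
    n_half = max(n_per_class // 2, 1)
    neg = generate_population(NONINVASIVE_ARCHETYPES, n_half, seed=seed)

    n_shared = int(round(INVASIVE_SHARED_FRACTION * n_per_class))
    pos_shared = generate_population(
        NONINVASIVE_ARCHETYPES, max(n_shared // 2, 1), seed=seed + 1
    )
    pos_elong = generate_population(
        INVASIVE_ARCHETYPES, max(n_per_class - len(pos_shared), 1), seed=seed + 2
    )
    pos = pd.concat([pos_shared, pos_elong], ignore_index=True)

    neg, _ = assign_yap(neg, coupling, seed=seed + 3)
    pos, _ = assign_yap(pos, coupling, decoupled=decouple, seed=seed + 4)
    neg["invasive"] = False
    pos["invasive"] = True
    table = pd.concat([neg, pos], ignore_index=True)
    # interleave classes so seeded splits stay balanced
    table = table.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    table["cell_id"] = [f"c{i:05d}" for i in range(len(table))]
    return table


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    """Write a cell table using the canonical column schema."""
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing descriptor columns: {missing}")
    return table
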