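"""Quality filters for predicted domain models.

A predicted domain enters classification only if it looks like a confident,
ordered, globular domain. The battery mirrors the filters used to admit
domains into structure classifications:

* mean per-residue confidence (pLDDT) at or above 70, the conventional
  "confident model" cut;
* no single Long Unordered Region (LUR; a run of >=5 consecutive residues
  with pLDDT < 70) covering more than 30% of the domain;
* no more than 65% of residues outside secondary-structure elements;
* at least 40 residues and at least 3 secondary-structure elements, the
  classical minimum for a classifiable domain;
* packing density (mean number of neighbour residues within 5 A of each
  hydrophobic residue) not above a calibrated cut;
* solvent-excluded-surface area / volume quotient not above a calibrated
  cut — the quotient shrinks as a shape becomes more compact.

The two globularity cuts are 95th percentiles of the metric distributions
over a trusted reference set. The values obtained from the classified-domain
reference with the original tooling are 9.75 (packing) and 0.494 (SES/vol)
and ship as documented defaults, but because both metrics are
implementation-coupled the recommended path is recalibration via
:func:`calibrate_thresholds` on a reference set scored with *this* package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes, mesh_surface_area

from .model_io import StructureModel

__all__ = [
    "SSEAnnotation",
    "QCReport",
    "Thresholds",
    "MetricError",
    "mean_plddt",
    "find_lurs",
    "lur_verdict",
    "assign_ss",
    "order_metrics",
    "packing_density",
    "ses_area_volume",
    "calibrate_thresholds",
    "qc_verdict",
    "HYDROPHOBIC",
]

#: Strongly hydrophobic residues used for the packing-density metric.
HYDROPHOBIC = frozenset("AVLIMFWC")

#: van der Waals radii (A) by element; used for the SES grid.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


class MetricError(ValueError):
    """A QC metric is undefined for this model (e.g. no hydrophobic residues)."""


@dataclass
class SSEAnnotation:
    """Three-state secondary structure aligned to a model's residues.

    ``per_residue`` is a string over {H, E, C}; ``elements`` lists the
    maximal cleaned runs as ``(kind, start, stop)`` with 0-based inclusive
    positions into the annotated model.
    """

    per_residue: str
    elements: list[tuple[str, int, int]]


@dataclass
class Thresholds:
    """All QC cuts. Inequality direction follows the filter definitions:

    mean pLDDT and size/SSE counts are lower bounds (``>=``); the LUR and
    unordered fractions are strict upper bounds (``>`` fails); the two
    globularity metrics fail when they exceed the calibrated percentile cut.
    """

    min_mean_plddt: float = 70.0
    lur_min_len: int = 5
    lur_plddt_cut: float = 70.0
    max_single_lur_fraction: float = 0.30
    max_unordered_fraction: float = 0.65
    min_residues: int = 40
    min_sses: int = 3
    max_packing_density: float = 9.75
    max_ses_per_volume: float = 0.494
    calibration_percentile: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.calibration_percentile <= 1.0):
            raise ValueError("calibration_percentile must be in (0, 1]")


@dataclass
class QCReport:
    """All filter metrics for one domain plus the verdict.

    ``verdict`` is "pass" iff ``failed_rules`` is empty; every violated rule
    is recorded, not just the first.
    """

    domain_id: str
    mean_plddt: float
    n_residues: int
    max_single_lur_fraction: float
    unordered_fraction: float
    n_sses: int
    packing_density: float
    ses_area: float
    ses_volume: float
    ses_per_volume: float
    failed_rules: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "pass" if not self.failed_rules else "fail"


def mean_plddt(model: StructureModel) -> float:
    """Arithmetic mean pLDDT over the constituent residues."""
    return float(np.mean(model.plddt))


def find_lurs(plddt: Sequence[float], min_len: int = 5,
              cut: float = 70.0) -> list[tuple[int, int]]:
    """Long Unordered Regions in a per-residue confidence series.

    Returns maximal runs (0-based inclusive ``(start, stop)`` positions) of
    consecutive values strictly below ``cut`` with run length >= ``min_len``.
    """
    runs: list[tuple[int, int]] = []
    start = None
    series = list(plddt)
    for i, v in enumerate(series):
        if v < cut:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(series) - start >= min_len:
        runs.append((start, len(series) - 1))
    return runs


def max_single_lur_fraction(model: StructureModel,
                            thresholds: Thresholds | None = None) -> float:
    t = thresholds or Thresholds()
    lurs = find_lurs(model.plddt, t.lur_min_len, t.lur_plddt_cut)
    if not lurs:
        return 0.0
    return max(b - a + 1 for a, b in lurs) / model.n_residues


def lur_verdict(model: StructureModel,
                thresholds: Thresholds | None = None) -> str:
    """Fail iff any *single* LUR covers more than 30% of the domain.

    Several shorter LURs jointly exceeding 30% do not fail this rule; the
    unordered-fraction rule handles pervasive disorder.
    """
    t = thresholds or Thresholds()
    frac = max_single_lur_fraction(model, t)
    return "fail" if frac > t.max_single_lur_fraction else "pass"


# -- secondary structure ---------------------------------------------------

_HB_Q1Q2_F = 0.084 * 332.0  # electrostatic H-bond model, kcal/mol * A
_HB_CUT = -0.5


def _hbond_matrix(model: StructureModel) -> np.ndarray:
    """Backbone H-bond matrix: ``hb[i, j]`` true if the N-H of residue i
    donates to the C=O of residue j, by the classic electrostatic model
    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) < -0.5 kcal/mol.

    The amide H is reconstructed on the bisector of the C(i-1)->N and CA->N
    directions; the chain's first residue and prolines have no donor.
    """
    n = model.n_residues
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, res in enumerate(model.residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            if name not in res.atoms:
                raise MetricError(
                    f"residue {res.seq_index} lacks backbone atom {name}")
            arr[i] = res.atoms[name]
    H = np.full((n, 3), np.nan)
    seq = model.sequence
    idx = model.seq_indices
    for i in range(1, n):
        if seq[i] == "P" or idx[i] != idx[i - 1] + 1:
            continue  # no amide H, or chain break
        d1 = N[i] - C[i - 1]
        d2 = N[i] - CA[i]
        u = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        H[i] = N[i] + u / np.linalg.norm(u) * 1.0
    hb = np.zeros((n, n), dtype=bool)
    donors = [i for i in range(n) if not np.isnan(H[i, 0])]
    for i in donors:
        d_on = np.linalg.norm(O - N[i], axis=1)
        d_ch = np.linalg.norm(C - H[i], axis=1)
        d_oh = np.linalg.norm(O - H[i], axis=1)
        d_cn = np.linalg.norm(C - N[i], axis=1)
        with np.errstate(divide="ignore"):
            energy = _HB_Q1Q2_F * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if energy[j] < _HB_CUT:
                hb[i, j] = True
    return hb


def _clean_elements(states: list[str], min_helix: int = 4,
                    min_strand: int = 3) -> str:
    """Element cleanup: absorb single-residue gaps inside an element, then
    drop helices shorter than 4 and strands shorter than 3 residues."""
    s = states[:]
    n = len(s)
    for i in range(1, n - 1):
        if s[i] == "C" and s[i - 1] == s[i + 1] and s[i - 1] in "HE":
            s[i] = s[i - 1]
    out = s[:]
    i = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if s[i] == "H" and j - i < min_helix:
            out[i:j] = ["C"] * (j - i)
        elif s[i] == "E" and j - i < min_strand:
            out[i:j] = ["C"] * (j - i)
        i = j
    return "".join(out)


def _elements_from_string(ss: str) -> list[tuple[str, int, int]]:
    elements = []
    i = 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i]:
            j += 1
        if ss[i] in "HE":
            elements.append((ss[i], i, j - 1))
        i = j
    return elements


def assign_ss(model: StructureModel) -> SSEAnnotation:
    """Three-state secondary structure from backbone H-bond geometry.

    Kabsch–Sander-style: runs of i->i+4 H-bonds make helix; bridge-paired
    H-bond ladders make strand; everything else is coil. Helix takes
    precedence where the patterns overlap. The raw per-residue states are
    then cleaned (:func:`_clean_elements`) so that elements have the minimal
    lengths a curator would accept. Deterministic.
    """
    n = model.n_residues
    hb = _hbond_matrix(model)
    states = ["C"] * n
    # 4-turns: N-H of i+4 to C=O of i; two consecutive turns -> helix core
    turn4 = [i for i in range(n - 4) if hb[i + 4, i]]
    turnset = set(turn4)
    for i in turn4:
        if i + 1 in turnset:
            for k in range(i + 1, i + 5):
                states[k] = "H"
    # bridges (parallel / antiparallel ladders) -> strand
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            antiparallel = (hb[i, j] and hb[j, i]) or (
                hb[i - 1, j + 1] and hb[j - 1, i + 1])
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (
                hb[j - 1, i] and hb[i, j + 1])
            if antiparallel or parallel:
                for k in (i, j):
                    if states[k] == "C":
                        states[k] = "E"
    cleaned = _clean_elements(states)
    return SSEAnnotation(cleaned, _elements_from_string(cleaned))


def order_metrics(ss: SSEAnnotation) -> tuple[float, int]:
    """(fraction of residues outside elements, number of elements)."""
    n = len(ss.per_residue)
    if n == 0:
        return 1.0, 0
    unordered = ss.per_residue.count("C") / n
    return unordered, len(ss.elements)


# -- globularity -----------------------------------------------------------

def packing_density(model: StructureModel, cutoff: float = 5.0,
                    hydrophobic: frozenset[str] = HYDROPHOBIC) -> float:
    """Mean number of neighbour residues within ``cutoff`` A of each
    hydrophobic residue.

    Residues i and j are neighbours when any heavy-atom pair is within the
    cutoff; sequence neighbours count. Undefined (raises
    :class:`MetricError`) when the model has no hydrophobic residue.
    """
    hydro = [i for i, aa in enumerate(model.sequence) if aa in hydrophobic]
    if not hydro:
        raise MetricError("packing density undefined: no hydrophobic residues")
    coords, owner = model.heavy_atoms()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    neighbours: dict[int, set[int]] = {i: set() for i in range(model.n_residues)}
    for a, b in pairs:
        ra, rb = owner[a], owner[b]
        if ra != rb:
            neighbours[ra].add(rb)
            neighbours[rb].add(ra)
    return float(np.mean([len(neighbours[i]) for i in hydro]))


def ses_area_volume(model: StructureModel, probe_radius: float = 1.4,
                    voxel: float = 0.4) -> tuple[float, float]:
    """Solvent-excluded surface area (A^2) and enclosed volume (A^3).

    Grid construction: the solvent-accessible solid is the union of atoms
    inflated by the probe radius; eroding it back by the probe (morphological
    closing of the vdW union) leaves the solvent-excluded solid. The signed
    field of the accessible solid is exact near its boundary (distance to the
    nearest inflated atom); the erosion uses a Euclidean distance transform.
    Volume is the voxel count of the solid; area comes from a
    marching-cubes triangulation of the eroded level set.
    """
    coords, _ = model.heavy_atoms()
    radii = np.array([
        VDW_RADII.get(name[:1], 1.70)
        for res in model.residues for name in res.atoms
    ])
    if len(coords) > 1 and np.allclose(coords, coords[0], atol=1e-6):
        raise MetricError("degenerate structure: all atoms coincide")
    margin = float(radii.max() + probe_radius + 3 * voxel)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    # signed field of the solvent-accessible solid: min_i |x-c_i|-(r_i+rp)
    f = np.full(shape, np.inf, dtype=np.float32)
    axes = [lo[d] + voxel * np.arange(shape[d]) for d in range(3)]
    for c, r in zip(coords, radii):
        rr = r + probe_radius
        reach = rr + 2 * voxel
        sl = []
        ax_local = []
        for d in range(3):
            i0 = max(0, int((c[d] - reach - lo[d]) / voxel))
            i1 = min(shape[d], int((c[d] + reach - lo[d]) / voxel) + 2)
            sl.append(slice(i0, i1))
            ax_local.append(axes[d][i0:i1] - c[d])
        dx2 = ax_local[0][:, None, None] ** 2
        dy2 = ax_local[1][None, :, None] ** 2
        dz2 = ax_local[2][None, None, :] ** 2
        dist = np.sqrt(dx2 + dy2 + dz2, dtype=np.float32)
        region = f[tuple(sl)]
        np.minimum(region, dist - rr, out=region)
    sas = f <= 0.0
    if not sas.any():
        raise MetricError("degenerate structure: empty accessible solid")
    # signed distance to the accessible surface: exact (f) outside, EDT inside
    dt_in = ndimage.distance_transform_edt(sas, sampling=voxel)
    signed = np.where(sas, np.minimum(f, 0.5 * voxel - dt_in), f)
    level = -probe_radius
    solid = signed <= level
    volume = float(solid.sum()) * voxel ** 3
    if volume == 0.0:
        raise MetricError("degenerate structure: empty excluded solid")
    verts, faces, _, _ = marching_cubes(
        signed, level=level, spacing=(voxel, voxel, voxel))
    area = float(mesh_surface_area(verts, faces))
    return area, volume


def calibrate_thresholds(reference_reports: Iterable[QCReport],
                         percentile: float = 0.95,
                         base: Thresholds | None = None) -> Thresholds:
    """Set the two globularity cuts from a trusted reference distribution.

    The cut is the empirical ``percentile`` quantile (linear interpolation
    between order statistics) of the reference packing densities and SES/vol
    quotients; every other threshold keeps its default. Requires >= 20
    reference reports.
    """
    reports = list(reference_reports)
    if len(reports) < 20:
        raise ValueError(f"need >=20 reference reports, got {len(reports)}")
    packing = np.array([r.packing_density for r in reports], dtype=float)
    sespv = np.array([r.ses_per_volume for r in reports], dtype=float)
    t = base or Thresholds()
    return replace(
        t,
        max_packing_density=float(np.quantile(packing, percentile)),
        max_ses_per_volume=float(np.quantile(sespv, percentile)),
        calibration_percentile=percentile,
    )


def qc_verdict(model: StructureModel, thresholds: Thresholds | None = None,
               ss: SSEAnnotation | None = None,
               domain_id: str | None = None) -> QCReport:
    """Run the full QC battery and record every violated rule.

    ``ss`` allows ingesting an externally computed per-residue secondary
    structure (e.g. from a DSSP run) in place of the built-in assigner.
    Metric errors (undefined packing density, degenerate surfaces) are
    recorded as failures of the corresponding rule, so a domain the metrics
    cannot vouch for is conservatively rejected.
    """
    t = thresholds or Thresholds()
    failed: list[str] = []
    mp = mean_plddt(model)
    if mp < t.min_mean_plddt:
        failed.append("min_mean_plddt")
    lur_frac = max_single_lur_fraction(model, t)
    if lur_frac > t.max_single_lur_fraction:
        failed.append("max_single_lur_fraction")
    if ss is None:
        ss = assign_ss(model)
    if len(ss.per_residue) != model.n_residues:
        raise ValueError("secondary structure annotation length mismatch")
    unordered, n_sses = order_metrics(ss)
    if unordered > t.max_unordered_fraction:
        failed.append("max_unordered_fraction")
    if model.n_residues < t.min_residues:
        failed.append("min_residues")
    if n_sses < t.min_sses:
        failed.append("min_sses")
    try:
        packing = packing_density(model)
        if packing > t.max_packing_density:
            failed.append("max_packing_density")
    except MetricError:
        packing = math.nan
        failed.append("max_packing_density")
    try:
        area, volume = ses_area_volume(model)
        sespv = area / volume
        if sespv > t.max_ses_per_volume:
            failed.append("max_ses_per_volume")
    except MetricError:
        area = volume = sespv = math.nan
        failed.append("max_ses_per_volume")
    return QCReport(
        domain_id=domain_id or model.protein_id,
        mean_plddt=mp,
        n_residues=model.n_residues,
        max_single_lur_fraction=lur_frac,
        unordered_fraction=unordered,
        n_sses=n_sses,
        packing_density=packing,
        ses_area=area,
        ses_volume=volume,
        ses_per_volume=sespv,
        failed_rules=failed,
    )
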