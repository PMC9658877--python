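"""Oligomer geometry: cyclic symmetry, open/closed state, buried interfaces,
axial pore profile, and Calpha-geometry secondary structure.

Symmetry is estimated from the rigid rotations fitting each subunit onto its
ring neighbour (ring order by centroid azimuth about the plane normal of the
chain centroids).  Interface areas use a deterministic Shrake-Rupley SASA.
Secondary structure uses Calpha-distance windows only (no hydrogen bonds), so
reduced and synthetic models are supported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import EmptySelectionError, NotSymmetricError
from .structure_io import AssemblyModel
from .superposition import kabsch_fit

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
FALLBACK_RADIUS = 1.8
PROBE_RADIUS = 1.4

# Calpha-distance windows (A) for the geometric secondary-structure call
HELIX_D13 = (5.0, 0.6)
HELIX_D14 = (6.2, 0.7)
STRAND_D13 = (6.7, 0.6)
STRAND_MIN_D14 = 8.0     # low-curvature requirement for strands
GAP_CUTOFF = 4.5         # consecutive Calpha beyond this breaks runs
HELIX_MIN_RUN = 4
STRAND_MIN_RUN = 3


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper()[:1], FALLBACK_RADIUS)


@dataclass
class SymmetryEstimate:
    order: int
    axis: np.ndarray            # unit vector
    angle_per_step: float       # degrees
    symmetry_rmsd: float
    closed: bool
    interfaces: list[tuple[tuple[str, str], float]]  # adjacent pair -> A^2/subunit
    ring_order: list[str] = field(default_factory=list)
    center: np.ndarray = None

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "axis": self.axis.tolist(),
            "angle_per_step": self.angle_per_step,
            "symmetry_rmsd": self.symmetry_rmsd,
            "closed": self.closed,
            "interfaces": [{"pair": list(p), "buried_area": a} for p, a in self.interfaces],
            "ring_order": list(self.ring_order),
        }


@dataclass
class PoreProfile:
    samples: list[tuple[float, float]]  # (z along axis, min free radius)
    min_radius: float
    z_at_min: float

    def to_dict(self) -> dict:
        return {"samples": [[z, r] for z, r in self.samples],
                "min_radius": self.min_radius, "z_at_min": self.z_at_min}


@dataclass
class SsString:
    """Per-residue secondary-structure codes (H/E/C) for one chain."""

    codes: str
    gap_breaks: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.codes)

    def fractions(self) -> dict[str, float]:
        n = max(len(self.codes), 1)
        return {c: 100.0 * self.codes.count(c) / n for c in "HEC"}


@dataclass
class OpenCall:
    closed: bool
    weakest_pair: tuple[str, str] | None
    min_area: float
    median_area: float
    rel_cutoff: float
    abs_cutoff: float

    def to_dict(self) -> dict:
        return {"closed": self.closed,
                "weakest_pair": list(self.weakest_pair) if self.weakest_pair else None,
                "min_area": self.min_area, "median_area": self.median_area,
                "rel_cutoff": self.rel_cutoff, "abs_cutoff": self.abs_cutoff}


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley with a deterministic golden-spiral point set)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = PROBE_RADIUS, points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = coords.shape[0]
    ext = radii + probe
    sphere = _sphere_points(points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_ext = ext.max()
    for i in range(n):
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                      if j != i
                      and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        if not neighbours:
            areas[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        test = coords[i] + ext[i] * sphere
        nb = coords[neighbours]
        nr = ext[neighbours]
        d2 = ((test[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * (1.0 - buried.mean())
    return areas


def _chain_coords_radii(model: AssemblyModel, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
    chain = model.chain(chain_id)
    coords, radii = [], []
    for residue in chain.residues:
        for atom in residue.atoms:
            coords.append(atom.position)
            radii.append(vdw_radius(atom.element))
    return np.asarray(coords), np.asarray(radii)


def interface_area(model: AssemblyModel, chain_a: str, chain_b: str,
                   probe: float = PROBE_RADIUS, points: int = 960) -> float:
    """Buried area per subunit for a chain pair (A^2), clamped at 0.

    Mean over the two chains of (isolated SASA - SASA in the pair context).
    """
    ca, ra = _chain_coords_radii(model, chain_a)
    cb, rb = _chain_coords_radii(model, chain_b)
    iso_a = shrake_rupley(ca, ra, probe, points).sum()
    iso_b = shrake_rupley(cb, rb, probe, points).sum()
    pair = shrake_rupley(np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, points)
    in_pair_a = pair[:len(ca)].sum()
    in_pair_b = pair[len(ca):].sum()
    buried = 0.5 * ((iso_a - in_pair_a) + (iso_b - in_pair_b))
    return max(0.0, float(buried))


# ---------------------------------------------------------------------------
# Symmetry
# ---------------------------------------------------------------------------

def _chain_ca_maps(model: AssemblyModel) -> dict[str, dict[int, np.ndarray]]:
    out = {}
    for chain in model.chains:
        m = {}
        for residue in chain.residues:
            ca = residue.ca()
            if ca is not None:
                m[residue.number] = ca.position
        out[chain.chain_id] = m
    return out


def _ring_order(model: AssemblyModel) -> tuple[list[str], np.ndarray]:
    """Chain ids in cyclic order by centroid azimuth; first file chain first."""
    ids = model.chain_ids
    centroids = np.array([model.ca_coords(cid).mean(axis=0) for cid in ids])
    center = centroids.mean(axis=0)
    rel = centroids - center
    _, vecs = np.linalg.eigh(rel.T @ rel)
    normal = vecs[:, 0]          # smallest-variance direction = ring normal
    u, v = vecs[:, 2], vecs[:, 1]
    azimuth = np.arctan2(rel @ v, rel @ u)
    order = list(np.argsort(azimuth, kind="stable"))
    start = order.index(0)
    order = order[start:] + order[:start]
    return [ids[k] for k in order], center


def _step_rotation(ca_a: dict[int, np.ndarray], ca_b: dict[int, np.ndarray]
                   ) -> tuple[np.ndarray, float]:
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise NotSymmetricError("fewer than 3 shared residues between adjacent chains")
    P = np.array([ca_a[r] for r in common])
    Q = np.array([ca_b[r] for r in common])
    fit = kabsch_fit(P, Q)
    if fit.rmsd > 10.0:
        raise NotSymmetricError(
            f"adjacent chains superpose at {fit.rmsd:.2f} A RMSD (> 10 A); not Cn symmetric")
    rotvec = Rotation.from_matrix(fit.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    axis = rotvec / angle if angle > 1e-12 else np.array([0.0, 0.0, 1.0])
    return axis, angle


def estimate_symmetry(model: AssemblyModel, probe: float = PROBE_RADIUS,
                      points: int = 960,
                      rel_cutoff: float = 0.25, abs_cutoff: float = 200.0) -> SymmetryEstimate:
    """Cyclic-symmetry estimate of a closed or nearly closed homo-oligomer.

    Per-step rotations come from fitting each chain onto its ring neighbour;
    the reported axis is the mean rotation axis oriented so that the axial
    third moment of the atom distribution is non-negative (making the sign,
    and hence the pore profile, invariant under global rigid motions).
    """
    n = model.n_chains
    if n < 3:
        raise NotSymmetricError(f"need >= 3 chains for a Cn estimate, got {n}")
    ring, _ = _ring_order(model)
    ca_maps = _chain_ca_maps(model)

    axes, angles = [], []
    for k in range(n):
        a, b = ring[k], ring[(k + 1) % n]
        axis, angle = _step_rotation(ca_maps[a], ca_maps[b])
        if axes and np.dot(axis, axes[0]) < 0:
            axis, angle = -axis, 2.0 * np.pi - angle
        axes.append(axis)
        angles.append(angle)
    mean_axis = np.mean(axes, axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    # circular mean of the per-step angles
    angle = float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))) % (2 * np.pi)

    coords = model.coords()
    center = coords.mean(axis=0)
    z = (coords - center) @ mean_axis
    if np.sum(z ** 3) < 0:
        mean_axis = -mean_axis
        angle = 2.0 * np.pi - angle

    # self-similarity under a one-step rotation, tried in both ring directions
    rot = Rotation.from_rotvec(mean_axis * angle).as_matrix()
    sq_fwd, sq_rev, cnt = 0.0, 0.0, 0
    for k in range(n):
        a = ring[k]
        nxt, prv = ring[(k + 1) % n], ring[(k - 1) % n]
        common_f = sorted(set(ca_maps[a]) & set(ca_maps[nxt]))
        common_r = sorted(set(ca_maps[a]) & set(ca_maps[prv]))
        Pa = np.array([ca_maps[a][r] for r in common_f])
        rotated = (Pa - center) @ rot.T + center
        sq_fwd += float(np.sum((rotated - np.array([ca_maps[nxt][r] for r in common_f])) ** 2))
        Pa2 = np.array([ca_maps[a][r] for r in common_r])
        rotated2 = (Pa2 - center) @ rot.T + center
        sq_rev += float(np.sum((rotated2 - np.array([ca_maps[prv][r] for r in common_r])) ** 2))
        cnt += len(common_f)
    symmetry_rmsd = float(np.sqrt(min(sq_fwd, sq_rev) / cnt))

    interfaces = []
    for k in range(n):
        pair = (ring[k], ring[(k + 1) % n])
        interfaces.append((pair, interface_area(model, *pair, probe=probe, points=points)))

    # report the step magnitude (0, 180]; the axis stays in its canonical
    # orientation so downstream profiles are rigid-motion invariant
    step_deg = math.degrees(angle if angle <= math.pi else 2.0 * math.pi - angle)
    est = SymmetryEstimate(order=n, axis=mean_axis,
                           angle_per_step=step_deg,
                           symmetry_rmsd=symmetry_rmsd, closed=True,
                           interfaces=interfaces, ring_order=ring, center=center)
    est.closed = detect_open_assembly(model, est, rel_cutoff=rel_cutoff,
                                      abs_cutoff=abs_cutoff).closed
    return est


def detect_open_assembly(model: AssemblyModel, sym: SymmetryEstimate,
                         rel_cutoff: float = 0.25, abs_cutoff: float = 200.0) -> OpenCall:
    """Open/closed call: open when the weakest adjacent interface is small
    both relative to the median interface and in absolute terms."""
    areas = np.array([a for _, a in sym.interfaces])
    pairs = [p for p, _ in sym.interfaces]
    k = int(np.argmin(areas))
    min_area = float(areas[k])
    median = float(np.median(areas))
    is_open = (min_area < rel_cutoff * median) and (min_area < abs_cutoff)
    return OpenCall(closed=not is_open, weakest_pair=pairs[k], min_area=min_area,
                    median_area=median, rel_cutoff=rel_cutoff, abs_cutoff=abs_cutoff)


# ---------------------------------------------------------------------------
# Pore profile
# ---------------------------------------------------------------------------

def pore_profile(model: AssemblyModel, sym: SymmetryEstimate,
                 step: float = 1.0, max_radius: float = 30.0) -> PoreProfile:
    """Minimum free radius around the symmetry axis per axial slab."""
    coords = model.coords()
    radii = np.array([vdw_radius(e) for e in model.elements()])
    center = sym.center if sym.center is not None else coords.mean(axis=0)
    axis = sym.axis
    z = (coords - center) @ axis
    radial = np.linalg.norm((coords - center) - np.outer(z, axis), axis=1)
    free = radial - radii

    samples = []
    z0, z1 = float(z.min()), float(z.max())
    grid = np.arange(z0, z1 + step / 2, step)
    for zc in grid:
        mask = np.abs(z - zc) <= step / 2
        if not mask.any():
            r = max_radius
        else:
            r = float(np.clip(free[mask].min(), 0.0, max_radius))
        samples.append((float(zc), r))
    radii_only = [r for _, r in samples]
    kmin = int(np.argmin(radii_only))
    return PoreProfile(samples=samples, min_radius=radii_only[kmin],
                       z_at_min=samples[kmin][0])


# ---------------------------------------------------------------------------
# Secondary structure (Calpha geometry)
# ---------------------------------------------------------------------------

def assign_ss(ca_coords: np.ndarray) -> SsString:
    """H/E/C per residue from Calpha-distance windows.

    Helix: d(i,i+3) and d(i,i+4) inside their windows over a run of >= 4
    consecutive start positions.  Strand: d(i,i+2) inside its window with low
    curvature (d(i,i+3) extended) over a run of >= 3.  Chain gaps
    (consecutive Calpha > 4.5 A apart) break runs and are flagged.
    """
    X = np.asarray(ca_coords, float)
    n = X.shape[0]
    codes = np.full(n, "C", dtype="<U1")
    if n < 5:
        return SsString("".join(codes))

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(X[j] - X[i]))

    gap_after = np.array([d(i, i + 1) > GAP_CUTOFF for i in range(n - 1)])
    gap_breaks = tuple(int(i) for i in np.nonzero(gap_after)[0])

    def contiguous(i: int, j: int) -> bool:
        return not gap_after[i:j].any()

    helix_flag = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if not contiguous(i, i + 4):
            continue
        if (abs(d(i, i + 3) - HELIX_D13[0]) <= HELIX_D13[1]
                and abs(d(i, i + 4) - HELIX_D14[0]) <= HELIX_D14[1]):
            helix_flag[i] = True

    strand_flag = np.zeros(n, dtype=bool)
    for i in range(n - 2):
        if not contiguous(i, i + 2):
            continue
        if abs(d(i, i + 2) - STRAND_D13[0]) > STRAND_D13[1]:
            continue
        if i + 3 < n and contiguous(i, i + 3) and d(i, i + 3) < STRAND_MIN_D14:
            continue
        strand_flag[i] = True

    def runs(flags: np.ndarray) -> list[tuple[int, int]]:
        out, start = [], None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(flags) - 1))
        return out

    for start, end in runs(strand_flag):
        if end - start + 1 >= STRAND_MIN_RUN:
            codes[start:end + 3] = "E"
    for start, end in runs(helix_flag):
        if end - start + 1 >= HELIX_MIN_RUN:
            codes[start:end + 5] = "H"   # helix takes precedence over strand
    return SsString("".join(codes), gap_breaks=gap_breaks)
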