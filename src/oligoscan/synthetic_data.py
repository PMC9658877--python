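"""Seeded generators for every input the pipeline consumes.

The generated models are Calpha-only toy folds with a helical body (the
oligomerization domain stand-in, mapped as BTB), a short connector (hinge)
and a strand-bearing body (mapped as CTD).  Assemblies are exact Cn rings
plus optional coordinate noise and an optional radially displaced ("open")
subunit.  PAE matrices have block structure with configurable per-class
means, and trajectories superpose thermal noise on an explicit BTB-vs-CTD
rotation mode.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly_geometry import SsString
from .confidence import PaeMatrix
from .errors import OligoscanError
from .md_analysis import Trajectory
from .structure_io import (AssemblyModel, AtomRecord, Chain, DomainMap,
                           DomainSpan, Residue, write_models, write_structure)

MIN_DOMAIN_SIZE = 8

DEFAULT_BLOCK_MEANS = {
    "intra-BTB": 4.0, "intra-CTD": 4.0,
    "inter-BTB": 6.0, "inter-CTD": 6.0,
    "cross-domain": 8.0, "other": 15.0, "nonadjacent": 20.0,
}

#: PAE block means producing each reliability regime (with noise ~1 A)
REGIME_MEANS = {
    "reliable": {**DEFAULT_BLOCK_MEANS},
    "partial": {**DEFAULT_BLOCK_MEANS, "inter-BTB": 10.0, "inter-CTD": 10.0},
    "unreliable": {**DEFAULT_BLOCK_MEANS, "inter-BTB": 25.0, "inter-CTD": 25.0},
}
REGIME_LABELS = {
    "reliable": ("S", "R"),
    "partial": ("S", "PR"),
    "unreliable": ("U", "U"),
}


@dataclass
class SyntheticSpec:
    n_chains: int = 5
    btb_residues: int = 24
    hinge_residues: int = 4
    ctd_residues: int = 30
    ring_radius: float = 11.0
    noise_sigma: float = 0.0
    pae_block_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_MEANS))
    pae_noise: float = 0.5
    open_displacement: float = 0.0
    interdomain_rotation: float = 0.0   # degrees, trajectory mode amplitude
    n_frames: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains, "btb_residues": self.btb_residues,
            "hinge_residues": self.hinge_residues, "ctd_residues": self.ctd_residues,
            "ring_radius": self.ring_radius, "noise_sigma": self.noise_sigma,
            "pae_block_means": dict(self.pae_block_means), "pae_noise": self.pae_noise,
            "open_displacement": self.open_displacement,
            "interdomain_rotation": self.interdomain_rotation,
            "n_frames": self.n_frames, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        return cls(**data)


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_points(n: int, z0: float) -> np.ndarray:
    """Ideal alpha-helix Calpha trace: radius 2.3 A, rise 1.5 A, 100 deg/res."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), z0 + 1.5 * i])


def _strand_points(n: int, origin: np.ndarray, direction: int) -> np.ndarray:
    """Extended-strand zigzag: 3.3 A axial step, +-0.5 A out-of-plane."""
    i = np.arange(n)
    pts = np.tile(origin, (n, 1)).astype(float)
    pts[:, 0] += direction * 3.3 * i
    pts[:, 2] += 0.5 * (-1.0) ** i
    return pts


def _loop_points(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """Connector residues on an arc bulging out of the start->end line."""
    t = (np.arange(n) + 1) / (n + 1)
    base = start[None, :] * (1 - t[:, None]) + end[None, :] * t[:, None]
    bulge = 3.0 * np.sin(np.pi * t)
    base[:, 2] += bulge
    return base


def make_chain(spec: SyntheticSpec) -> tuple[AssemblyModel, SsString, DomainMap]:
    """Single-chain Calpha model with ground-truth SS labels and domain map.

    Residues are numbered 1..N; the helical body is mapped as BTB, the
    connector as hinge, the strand body as CTD.  B-factors carry a synthetic
    per-residue pLDDT (uniform 70-95) drawn from the seed.
    """
    for name, size in (("btb", spec.btb_residues), ("ctd", spec.ctd_residues)):
        if size < MIN_DOMAIN_SIZE:
            raise OligoscanError(f"{name} domain needs >= {MIN_DOMAIN_SIZE} residues, got {size}")
    if spec.hinge_residues < 0:
        raise OligoscanError("hinge size must be >= 0")

    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    labels: list[str] = []

    helix = _helix_points(spec.btb_residues, z0=0.0)
    coords.extend(helix)
    labels.extend("H" * spec.btb_residues)

    # strand body: 8-residue strands joined by 3-residue loops, laddered in y
    ctd_top = helix[-1][2] + 7.0
    strand_len, loop_len = 8, 3
    remaining = spec.ctd_residues
    strand_specs: list[tuple[str, int]] = []
    while remaining > 0:
        if remaining >= strand_len:
            strand_specs.append(("E", strand_len))
            remaining -= strand_len
        else:
            strand_specs.append(("C", remaining))
            remaining = 0
            break
        if remaining > 0:
            take = min(loop_len, remaining)
            strand_specs.append(("C", take))
            remaining -= take

    ctd_coords: list[np.ndarray] = []
    ctd_labels: list[str] = []
    y, direction = 0.0, 1
    cursor = np.array([0.0, 0.0, ctd_top])
    for kind, size in strand_specs:
        if kind == "E":
            start = np.array([cursor[0], y, ctd_top])
            pts = _strand_points(size, start, direction)
            ctd_coords.extend(pts)
            ctd_labels.extend("E" * size)
            cursor = pts[-1]
            direction *= -1
            y += 4.8
        else:
            target = np.array([cursor[0], y, ctd_top])
            pts = _loop_points(cursor, target, size)
            ctd_coords.extend(pts)
            ctd_labels.extend("C" * size)
            if len(pts):
                cursor = pts[-1]

    ctd_arr = np.array(ctd_coords)
    # centre the strand body over the helix axis
    ctd_arr[:, :2] -= ctd_arr[:, :2].mean(axis=0)

    if spec.hinge_residues > 0:
        hinge = _loop_points(helix[-1], ctd_arr[0], spec.hinge_residues)
        coords.extend(hinge)
        labels.extend("C" * spec.hinge_residues)
    coords.extend(ctd_arr)
    labels.extend(ctd_labels)

    xyz = np.array(coords)
    xyz[:, :2] -= xyz[:, :2].mean(axis=0)
    xyz[:, 2] -= xyz[:, 2].mean()

    plddt = rng.uniform(70.0, 95.0, size=len(xyz))
    residues = []
    for i, (pos, conf) in enumerate(zip(xyz, plddt), start=1):
        atom = AtomRecord(serial=i, atom_name="CA", element="C", residue_name="ALA",
                          residue_number=i, insertion_code="", chain_id="A",
                          position=pos, occupancy=1.0, bfactor=round(float(conf), 2))
        residues.append(Residue("ALA", i, "", [atom]))
    model = AssemblyModel([Chain("A", residues)])

    btb_end = spec.btb_residues
    hinge_end = btb_end + spec.hinge_residues
    spans = [DomainSpan("BTB", 1, btb_end)]
    if spec.hinge_residues > 0:
        spans.append(DomainSpan("hinge", btb_end + 1, hinge_end))
    spans.append(DomainSpan("CTD", hinge_end + 1, hinge_end + spec.ctd_residues))
    return model, SsString("".join(labels)), DomainMap(spans)


_CHAIN_IDS = string.ascii_uppercase


def make_cn_assembly(chain: AssemblyModel, n: int, ring_radius: float,
                     noise_sigma: float = 0.0, open_displacement: float = 0.0,
                     seed: int = 0) -> AssemblyModel:
    """n copies placed by exact 360/n rotations about z at ``ring_radius``.

    Gaussian coordinate noise (sigma per component) is added after placement;
    if ``open_displacement`` > 0 the last chain is additionally translated
    radially outward by that amount, breaking its ring contacts.
    """
    if n < 1:
        raise OligoscanError("n must be >= 1")
    if n > len(_CHAIN_IDS):
        raise OligoscanError(f"at most {len(_CHAIN_IDS)} chains supported")
    rng = np.random.default_rng(seed)
    base = chain.chains[0]
    new_chains = []
    for k in range(n):
        angle = 2.0 * np.pi * k / n
        R = _rotz(angle)
        radial_dir = R @ np.array([1.0, 0.0, 0.0])
        shift = np.array([ring_radius, 0.0, 0.0])
        residues = []
        for residue in base.residues:
            atoms = []
            for atom in residue.atoms:
                pos = R @ (atom.position + shift)
                if open_displacement > 0 and k == n - 1:
                    pos = pos + open_displacement * radial_dir
                new_atom = atom.copy()
                new_atom.position = pos
                new_atom.chain_id = _CHAIN_IDS[k]
                atoms.append(new_atom)
            residues.append(Residue(residue.name, residue.number,
                                    residue.insertion_code, atoms))
        new_chains.append(Chain(_CHAIN_IDS[k], residues))
    model = AssemblyModel(new_chains)
    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=(model.atom_count, 3))
        model = model.with_coords(model.coords() + noise)
    return model


def make_pae(segmentation: list[tuple[str, int]], domain_map: DomainMap,
             block_means: dict[str, float], pae_noise: float = 0.5, seed: int = 0,
             pair_means: dict[frozenset, float] | None = None) -> PaeMatrix:
    """Block-structured PAE matrix with Gaussian noise (clipped at 0).

    Entry class: same-chain pairs split into intra-BTB / intra-CTD /
    cross-domain / ``other``; adjacent-chain pairs (cyclic file order) into
    inter-BTB / inter-CTD / ``other``; remaining chain pairs take the
    ``nonadjacent`` mean.  ``pair_means`` overrides every inter-chain entry of
    the named chain pairs (low-error quadrant fixtures).  The matrix is drawn
    entrywise, NOT symmetrized; the diagonal is fixed at 0.5 A.
    """
    rng = np.random.default_rng(seed)
    L = sum(n for _, n in segmentation)
    n_chains = len(segmentation)

    chain_of = np.concatenate([np.full(n, k, dtype=int)
                               for k, (_, n) in enumerate(segmentation)])
    domain_of = np.empty(L, dtype="<U8")
    offset = 0
    for _, count in segmentation:
        for local in range(count):
            domain_of[offset + local] = domain_map.domain_of(local + 1) or "none"
        offset += count

    def mean_for(key: str) -> float:
        if key in block_means:
            return block_means[key]
        return block_means.get("other", 15.0)

    means = np.empty((L, L))
    is_btb = domain_of == "BTB"
    is_ctd = domain_of == "CTD"
    same_chain = chain_of[:, None] == chain_of[None, :]
    diff = np.abs(chain_of[:, None] - chain_of[None, :])
    adjacent = (~same_chain) & ((diff == 1) | (diff == n_chains - 1))
    btb_pair = is_btb[:, None] & is_btb[None, :]
    ctd_pair = is_ctd[:, None] & is_ctd[None, :]
    cross = (is_btb[:, None] & is_ctd[None, :]) | (is_ctd[:, None] & is_btb[None, :])

    means[:] = mean_for("other")
    means[same_chain & btb_pair] = mean_for("intra-BTB")
    means[same_chain & ctd_pair] = mean_for("intra-CTD")
    means[same_chain & cross] = mean_for("cross-domain")
    means[adjacent & btb_pair] = mean_for("inter-BTB")
    means[adjacent & ctd_pair] = mean_for("inter-CTD")
    # adjacent-chain BTB<->CTD errors track the inter-domain confidence: a
    # rigidly predicted ring has low errors there too
    means[adjacent & cross] = 0.5 * (mean_for("inter-BTB") + mean_for("inter-CTD"))
    nonadj = ~same_chain & ~adjacent
    means[nonadj] = mean_for("nonadjacent")

    if pair_means:
        ids = [cid for cid, _ in segmentation]
        for pair, value in pair_means.items():
            a, b = sorted(pair)
            ka, kb = ids.index(a), ids.index(b)
            mask = ((chain_of[:, None] == ka) & (chain_of[None, :] == kb)) | \
                   ((chain_of[:, None] == kb) & (chain_of[None, :] == ka))
            means[mask] = value

    values = means + rng.normal(0.0, pae_noise, size=(L, L)) if pae_noise > 0 else means.copy()
    values = np.maximum(values, 0.0)
    np.fill_diagonal(values, 0.5)
    return PaeMatrix(values, list(segmentation))


def make_trajectory(model: AssemblyModel, n_frames: int, noise_schedule,
                    interdomain_rotation: float, domain_map: DomainMap,
                    seed: int = 0) -> Trajectory:
    """Frames with an oscillating CTD-vs-BTB rotation plus thermal noise.

    Frame t rotates every chain's CTD atoms about the z axis (through the
    assembly centroid) by ``interdomain_rotation * sin(2 pi t / n_frames)``
    degrees, then adds iid Gaussian noise sigma_t.  Frame 0 is the unperturbed
    starting model.
    """
    if n_frames < 1:
        raise OligoscanError("n_frames must be >= 1")
    schedule = np.asarray(noise_schedule, dtype=float)
    if schedule.shape != (n_frames,):
        raise OligoscanError(f"noise schedule must have length {n_frames}")
    rng = np.random.default_rng(seed)
    ctd_residues = set(domain_map.residues("CTD")) if domain_map.has("CTD") else set()
    coords0 = model.coords()
    center = coords0.mean(axis=0)
    ctd_mask = np.array([a.residue_number in ctd_residues for a in model.atoms()])

    frames = [model.copy()]
    for t in range(1, n_frames):
        angle = np.deg2rad(interdomain_rotation * np.sin(2.0 * np.pi * t / n_frames))
        R = _rotz(angle)
        xyz = coords0.copy()
        xyz[ctd_mask] = (xyz[ctd_mask] - center) @ R.T + center
        if schedule[t] > 0:
            xyz = xyz + rng.normal(0.0, schedule[t], size=xyz.shape)
        frames.append(model.with_coords(xyz))
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

def ground_truth(spec: SyntheticSpec, regime: str) -> dict:
    stability, grade = REGIME_LABELS[regime]
    return {
        "regime": regime,
        "stability": stability,
        "grade": grade,
        "closed": spec.open_displacement <= 0,
        "order": spec.n_chains,
        "angle_per_step": 360.0 / spec.n_chains,
    }


def write_fixture_set(spec: SyntheticSpec, outdir: str | Path,
                      protein_id: str = "synthetic", regime: str | None = None,
                      pair_means: dict[frozenset, float] | None = None) -> dict[str, Path]:
    """Write a complete plain-text fixture set for one assembly.

    Files: ``<id>_structure.pdb``, ``<id>_pae.json``, ``<id>_domains.tsv``,
    optionally ``<id>_trajectory.pdb`` (when ``spec.n_frames`` > 0) and
    ``<id>_truth.json`` (when a regime is named).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if regime is not None:
        spec.pae_block_means = dict(REGIME_MEANS[regime])
    chain, ss_truth, domain_map = make_chain(spec)
    assembly = make_cn_assembly(chain, spec.n_chains, spec.ring_radius,
                                noise_sigma=spec.noise_sigma,
                                open_displacement=spec.open_displacement,
                                seed=spec.seed)
    pae = make_pae(assembly.segmentation(), domain_map, spec.pae_block_means,
                   pae_noise=spec.pae_noise, seed=spec.seed + 1,
                   pair_means=pair_means)

    paths = {}
    paths["structure"] = outdir / f"{protein_id}_structure.pdb"
    write_structure(assembly, paths["structure"])
    paths["pae"] = outdir / f"{protein_id}_pae.json"
    with open(paths["pae"], "w") as handle:
        json.dump({"predicted_aligned_error": np.round(pae.values, 3).tolist()},
                  handle)
    paths["domains"] = outdir / f"{protein_id}_domains.tsv"
    domain_map.to_tsv(paths["domains"], protein=protein_id)

    if spec.n_frames > 0:
        traj = make_trajectory(assembly, spec.n_frames,
                               np.full(spec.n_frames, spec.noise_sigma or 0.3),
                               spec.interdomain_rotation, domain_map,
                               seed=spec.seed + 2)
        paths["trajectory"] = outdir / f"{protein_id}_trajectory.pdb"
        write_models(traj.frames, paths["trajectory"])

    truth = {"spec": spec.to_dict(), "ss": ss_truth.codes}
    if regime is not None:
        truth.update(ground_truth(spec, regime))
    paths["truth"] = outdir / f"{protein_id}_truth.json"
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
    return paths
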