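"""Trajectory post-processing: RMSD series against the starting model,
secondary-structure content evolution, and the closest-to-average frame."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly_geometry import assign_ss
from .errors import EmptySelectionError, TrajectoryFormatError
from .structure_io import AssemblyModel, DomainMap, read_models, select_atoms
from .superposition import kabsch_fit

#: trajectory-mean RMSD bands (A); the boundary value joins the larger band
LABEL_BANDS = ((3.0, "low"), (6.0, "limited"), (float("inf"), "high"))


def stability_label(mean_rmsd: float) -> str:
    """'low' (< 3 A), 'limited' (3 <= x < 6 A) or 'high' (>= 6 A)."""
    if mean_rmsd < 3.0:
        return "low"
    if mean_rmsd < 6.0:
        return "limited"
    return "high"


@dataclass
class Trajectory:
    frames: list[AssemblyModel]
    frame_times: np.ndarray | None = None   # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryFormatError("trajectory has no frames")
        ref = self.frames[0]
        ref_inventory = [(a.chain_id, a.residue_number, a.atom_name) for a in ref.atoms()]
        for k, frame in enumerate(self.frames[1:], start=1):
            inv = [(a.chain_id, a.residue_number, a.atom_name) for a in frame.atoms()]
            if inv != ref_inventory:
                raise TrajectoryFormatError(
                    f"model index {k}: atom inventory differs from model 0 "
                    f"({len(inv)} vs {len(ref_inventory)} atoms)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class RmsdSeries:
    values: np.ndarray
    label: str

    def to_dict(self) -> dict:
        return {"values": self.values.tolist(), "mean": float(self.values.mean()),
                "label": self.label}


@dataclass
class TrajectoryAnalysis:
    rmsd: dict[str, RmsdSeries]
    ss_fractions: np.ndarray          # (n_frames, 3): H%, E%, C%
    closest_frame: int

    def to_dict(self) -> dict:
        return {
            "rmsd": {k: v.to_dict() for k, v in self.rmsd.items()},
            "ss_fractions": self.ss_fractions.tolist(),
            "closest_frame": self.closest_frame,
            "labels": {k: v.label for k, v in self.rmsd.items()},
        }


def read_trajectory(path: str | Path) -> Trajectory:
    """One frame per MODEL record of a multi-model PDB file."""
    return Trajectory(frames=read_models(path))


def _selection_coords(model: AssemblyModel, chain_ids=None, domain=None,
                      domain_map: DomainMap | None = None,
                      atom_names=("CA",)) -> np.ndarray:
    sub = select_atoms(model, chain_ids=chain_ids, domain=domain,
                       domain_map=domain_map,
                       atom_names=set(atom_names) if atom_names else None)
    return sub.coords()


def rmsd_series(traj: Trajectory, reference: AssemblyModel | None = None,
                chain_ids=None, domain=None, domain_map: DomainMap | None = None,
                atom_names=("CA",), fit: bool = True,
                fit_domain: str | None = None) -> RmsdSeries:
    """Per-frame RMSD against the reference (default: frame 0) on a selection.

    With ``fit=True`` each frame is least-squares superposed on the selection
    before the RMSD is taken.  ``fit_domain`` superposes on a *different*
    domain instead (e.g. fit on the BTB, measure the CTD), which exposes
    relative inter-domain motions.  The stability label derives from the
    trajectory-mean RMSD (3 / 6 A bands).
    """
    ref = reference if reference is not None else traj.frames[0]
    sel = dict(chain_ids=chain_ids, domain=domain, domain_map=domain_map,
               atom_names=atom_names)
    ref_xyz = _selection_coords(ref, **sel)
    if ref_xyz.shape[0] == 0:
        raise EmptySelectionError("selection is empty in the reference")
    fit_sel = None
    if fit_domain is not None:
        fit_sel = dict(chain_ids=chain_ids, domain=fit_domain,
                       domain_map=domain_map, atom_names=atom_names)
        ref_fit = _selection_coords(ref, **fit_sel)
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        xyz = _selection_coords(frame, **sel)
        if xyz.shape != ref_xyz.shape:
            raise TrajectoryFormatError(
                f"frame {k}: selection size {xyz.shape[0]} != reference {ref_xyz.shape[0]}")
        if fit_sel is not None:
            transform = kabsch_fit(_selection_coords(frame, **fit_sel), ref_fit)
            diff = transform.apply(xyz) - ref_xyz
            values[k] = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
        elif fit and xyz.shape[0] >= 3:
            values[k] = kabsch_fit(xyz, ref_xyz).rmsd
        else:
            diff = xyz - ref_xyz
            values[k] = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return RmsdSeries(values=values, label=stability_label(float(values.mean())))


def ss_series(traj: Trajectory) -> np.ndarray:
    """Pooled secondary-structure percentages (H, E, C) per frame; rows sum to 100."""
    out = np.empty((traj.n_frames, 3))
    for k, frame in enumerate(traj.frames):
        counts = {"H": 0, "E": 0, "C": 0}
        total = 0
        for chain in frame.chains:
            ca = [r.ca() for r in chain.residues]
            coords = np.array([a.position for a in ca if a is not None])
            if coords.shape[0] == 0:
                continue
            ss = assign_ss(coords)
            for c in ss.codes:
                counts[c] += 1
            total += len(ss.codes)
        if total == 0:
            raise EmptySelectionError(f"frame {k}: no Calpha atoms")
        out[k] = [100.0 * counts[c] / total for c in "HEC"]
    return out


def closest_to_average(traj: Trajectory, chain_ids=None, domain=None,
                       domain_map: DomainMap | None = None,
                       atom_names=("CA",)) -> int:
    """Frame index closest (RMSD on the selection) to the fitted-average
    structure; frames are first superposed on frame 0; ties take the lowest
    index."""
    sel = dict(chain_ids=chain_ids, domain=domain, domain_map=domain_map,
               atom_names=atom_names)
    ref_xyz = _selection_coords(traj.frames[0], **sel)
    fitted = []
    for frame in traj.frames:
        xyz = _selection_coords(frame, **sel)
        if xyz.shape[0] >= 3:
            fit = kabsch_fit(xyz, ref_xyz)
            fitted.append(fit.apply(xyz))
        else:
            fitted.append(xyz)
    fitted = np.array(fitted)
    average = fitted.mean(axis=0)
    rmsds = np.sqrt(np.mean(np.sum((fitted - average) ** 2, axis=2), axis=1))
    # round so floating-point-level near-ties resolve to the lowest index
    return int(np.argmin(np.round(rmsds, 9)))


def analyze_trajectory(traj: Trajectory, domain_map: DomainMap | None = None,
                       reference: AssemblyModel | None = None) -> TrajectoryAnalysis:
    """Standard analysis bundle: global/BTB/CTD RMSD, SS evolution, closest frame."""
    rmsd = {"global": rmsd_series(traj, reference=reference)}
    if domain_map is not None:
        for dom in ("BTB", "CTD"):
            if domain_map.has(dom):
                rmsd[dom] = rmsd_series(traj, reference=reference, domain=dom,
                                        domain_map=domain_map)
    return TrajectoryAnalysis(rmsd=rmsd, ss_fractions=ss_series(traj),
                              closest_frame=closest_to_average(traj))
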