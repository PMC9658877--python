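"""Rigid-body superposition: closed-form least squares, outlier-rejecting
refinement, and symmetry-aware whole-oligomer fitting with a chain-mapping
search."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, StoichiometryError
from .structure_io import AssemblyModel

__all__ = ["SuperpositionResult", "kabsch_fit", "refine_fit", "oligomer_fit"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray           # 3x3, orthonormal, det +1
    translation: np.ndarray        # 3-vector
    rmsd: float
    atoms_aligned: int
    chain_mapping: dict[str, str] = field(default_factory=dict)
    cycles: int = 1
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)
    retained_mask: np.ndarray | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "atoms_aligned": self.atoms_aligned,
            "chain_mapping": dict(self.chain_mapping),
            "cycles": self.cycles,
            "warnings": list(self.warnings),
        }


def _kabsch_core(mobile: np.ndarray, target: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Optimal proper rotation/translation mapping mobile onto target."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    X, Y = P - pc, Q - qc
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    # collinear/degenerate point sets leave the rotation underdetermined
    degenerate = bool(S[1] <= 1e-9 * max(S[0], 1.0))
    return R, t, rmsd, degenerate


def _check_pair(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.ndim != 2 or P.shape[1] != 3 or Q.shape != P.shape:
        raise ValueError(f"coordinate sets must share shape (N, 3); got {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise EmptySelectionError(f"need >= 3 points for a rigid fit, got {P.shape[0]}")
    return P, Q


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rotation + translation over paired points.

    Correspondence is positional; the mirror solution is never returned
    (det(R) is forced to +1), so chiral mismatches surface as residual RMSD.
    """
    P, Q = _check_pair(mobile, target)
    R, t, rmsd, degenerate = _kabsch_core(P, Q)
    warn = ["degenerate (near-collinear) point set"] if degenerate else []
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               atoms_aligned=P.shape[0], cycles=1,
                               degenerate=degenerate, warnings=warn,
                               retained_mask=np.ones(P.shape[0], dtype=bool))


def refine_fit(mobile: np.ndarray, target: np.ndarray,
               max_cycles: int = 5, reject_sigma: float = 2.0) -> SuperpositionResult:
    """Iterative fit with sigma-based outlier rejection.

    Each cycle refits on the retained pairs then drops pairs whose deviation
    exceeds ``reject_sigma`` times the standard deviation of the retained
    deviations.  Stops when the retained set is stable, the fit has converged
    (spread ~ 0), or rejection would leave fewer than 3 pairs (in which case
    the previous cycle's result is returned with a warning).
    """
    P, Q = _check_pair(mobile, target)
    n = P.shape[0]
    retained = np.ones(n, dtype=bool)
    result: SuperpositionResult | None = None
    for cycle in range(1, max_cycles + 1):
        R, t, rmsd, degenerate = _kabsch_core(P[retained], Q[retained])
        result = SuperpositionResult(
            rotation=R, translation=t, rmsd=rmsd,
            atoms_aligned=int(retained.sum()), cycles=cycle,
            degenerate=degenerate,
            warnings=["degenerate (near-collinear) point set"] if degenerate else [],
            retained_mask=retained.copy())
        dev = np.linalg.norm(P @ R.T + t - Q, axis=1)
        spread = float(dev[retained].std())
        if spread < 1e-8:
            break  # converged; nothing meaningful left to reject
        keep = retained & (dev <= reject_sigma * spread)
        if int(keep.sum()) < 3:
            result.warnings.append(
                f"cycle {cycle}: rejection would retain {int(keep.sum())} < 3 pairs; "
                "keeping previous retained set")
            break
        if np.array_equal(keep, retained):
            break
        retained = keep
    assert result is not None
    return result


# ---------------------------------------------------------------------------
# Whole-oligomer fit
# ---------------------------------------------------------------------------

def _ca_by_resnum(model: AssemblyModel, chain_id: str) -> dict[int, np.ndarray]:
    out = {}
    for residue in model.chain(chain_id).residues:
        ca = residue.ca()
        if ca is not None:
            out[residue.number] = ca.position
    return out


def _candidate_mappings(n: int, search: str) -> list[tuple[int, ...]]:
    if search == "exhaustive":
        return list(itertools.permutations(range(n)))
    if search != "cyclic":
        raise ValueError(f"unknown search mode {search!r}")
    maps = []
    for s in range(n):
        maps.append(tuple((i + s) % n for i in range(n)))
        maps.append(tuple((s - i) % n for i in range(n)))
    # dedupe (n = 2 collapses forward/reverse)
    return sorted(set(maps))


def oligomer_fit(mobile: AssemblyModel, target: AssemblyModel,
                 search: str = "cyclic", base_chain: int = 0,
                 max_cycles: int = 5, reject_sigma: float = 2.0) -> SuperpositionResult:
    """Two-stage assembly superposition with chain-mapping search.

    Stage 1 fits one mobile monomer onto one target monomer (Calpha pairs
    shared by residue number) with outlier rejection; the retained residues
    define the aligned core.  Stage 2 enumerates chain bijections (``cyclic``:
    n rotations x 2 directions over chain order; ``exhaustive``: all n!)
    and returns the minimum-RMSD rigid fit of the full assembly on the core.
    """
    n = mobile.n_chains
    if n != target.n_chains:
        raise StoichiometryError(
            f"chain counts differ: {n} (mobile) vs {target.n_chains} (target)")
    if n < 2:
        raise StoichiometryError("oligomer_fit needs >= 2 chains")

    mob_ids, tar_ids = mobile.chain_ids, target.chain_ids
    mob_ca = [_ca_by_resnum(mobile, cid) for cid in mob_ids]
    tar_ca = [_ca_by_resnum(target, cid) for cid in tar_ids]

    # stage 1: monomer core
    common = sorted(set(mob_ca[base_chain]) & set(tar_ca[base_chain]))
    if len(common) < 3:
        raise StoichiometryError("empty common residue core between base monomers")
    P = np.array([mob_ca[base_chain][r] for r in common])
    Q = np.array([tar_ca[base_chain][r] for r in common])
    stage1 = refine_fit(P, Q, max_cycles=max_cycles, reject_sigma=reject_sigma)
    core = {r for r, kept in zip(common, stage1.retained_mask) if kept}

    # stage 2: assembly fit under each candidate chain mapping
    best: SuperpositionResult | None = None
    for mapping in _candidate_mappings(n, search):
        pairs_p, pairs_q = [], []
        for i, j in enumerate(mapping):
            shared = sorted((set(mob_ca[i]) & set(tar_ca[j])) & core)
            pairs_p.extend(mob_ca[i][r] for r in shared)
            pairs_q.extend(tar_ca[j][r] for r in shared)
        if len(pairs_p) < 3:
            continue
        fit = kabsch_fit(np.array(pairs_p), np.array(pairs_q))
        fit.chain_mapping = {mob_ids[i]: tar_ids[j] for i, j in enumerate(mapping)}
        fit.cycles = stage1.cycles
        if best is None or fit.rmsd < best.rmsd:
            best = fit
    if best is None:
        raise StoichiometryError("no chain mapping yields a usable aligned core")
    return best
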