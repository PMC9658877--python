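"""Predicted-aligned-error parsing and domain-decomposed reliability scoring.

The central statistic is, per block of residue pairs, the percentage of pairs
whose (symmetrized) expected error is strictly below a threshold (default
10 A).  Blocks are formed by crossing chain relation (same chain vs adjacent
chains) with domain membership (BTB vs CTD); an assembly is graded reliable
(R) when every block percentage is strictly above the reliable threshold
(default 65%), partially reliable (PR) when the intra blocks clear it and the
inter blocks stay above a lower configurable band, and unreliable (U)
otherwise.  Stability as an oligomer (S/U) follows from the grade.

Chain-pair quadrants of the matrix also drive a sub-stoichiometry inference:
chains are linked when their inter-chain block is confidently low-error and
the connected components of that graph are candidate sub-oligomers (e.g. a
5-chain prediction decomposing into 2+2+1 signals dimer propensity).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainMapError, PaeDialectError, PaeFormatError
from .structure_io import DomainMap

BLOCK_CLASSES = ("intra-BTB", "intra-CTD", "inter-BTB", "inter-CTD", "cross-domain")
#: classes that participate in grading (cross-domain is reported only)
GRADED_CLASSES = ("intra-BTB", "intra-CTD", "inter-BTB", "inter-CTD")

_OLIGOMER_NAMES = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
                   5: "pentamer", 6: "hexamer", 7: "heptamer", 8: "octamer"}


def oligomer_name(k: int) -> str:
    return _OLIGOMER_NAMES.get(k, f"{k}-mer")


@dataclass
class AnalysisConfig:
    """Thresholds and pooling conventions for the reliability statistics."""

    pae_threshold: float = 10.0       # A; pairs strictly below count as low-error
    reliable_percent: float = 65.0    # strict lower bound for grade R
    partial_percent: float = 40.0     # strict lower bound of the PR band (inter blocks)
    adjacency: str = "cyclic"         # 'cyclic' or 'all_pairs'
    pair_symmetrization: str = "mean"  # 'mean', 'min' or 'ordered'

    def __post_init__(self) -> None:
        if not (0 < self.partial_percent < self.reliable_percent < 100):
            raise ValueError("need 0 < partial_percent < reliable_percent < 100")
        if self.pae_threshold <= 0:
            raise ValueError("pae_threshold must be positive")
        if self.adjacency not in ("cyclic", "all_pairs"):
            raise ValueError(f"unknown adjacency mode {self.adjacency!r}")
        if self.pair_symmetrization not in ("mean", "min", "ordered"):
            raise ValueError(f"unknown symmetrization {self.pair_symmetrization!r}")

    def to_dict(self) -> dict:
        return {
            "pae_threshold": self.pae_threshold,
            "reliable_percent": self.reliable_percent,
            "partial_percent": self.partial_percent,
            "adjacency": self.adjacency,
            "pair_symmetrization": self.pair_symmetrization,
        }


@dataclass
class PaeMatrix:
    """L x L expected-error matrix with chain segmentation."""

    values: np.ndarray
    segmentation: list[tuple[str, int]]
    dialect_warning: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise PaeFormatError(f"PAE matrix must be square, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise PaeFormatError("PAE entries must be finite and >= 0")
        total = sum(n for _, n in self.segmentation)
        if total != self.values.shape[0]:
            raise PaeFormatError(
                f"segmentation totals {total} residues but matrix is {self.values.shape[0]}")
        if self.values.shape[0] and np.max(np.diag(self.values)) > 5.0:
            self.dialect_warning = True
            warnings.warn("PAE diagonal entries exceed 5 A; check matrix dialect",
                          stacklevel=2)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.segmentation)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.segmentation]

    def chain_slices(self) -> dict[str, slice]:
        out = {}
        offset = 0
        for cid, n in self.segmentation:
            out[cid] = slice(offset, offset + n)
            offset += n
        return out

    def submatrix(self, indices: np.ndarray,
                  segmentation: list[tuple[str, int]]) -> "PaeMatrix":
        """Restrict to a subset of flat residue indices (ascending)."""
        indices = np.asarray(indices, dtype=int)
        return PaeMatrix(self.values[np.ix_(indices, indices)], segmentation)

    def symmetrized(self, mode: str = "mean") -> np.ndarray:
        if mode == "mean":
            return 0.5 * (self.values + self.values.T)
        if mode == "min":
            return np.minimum(self.values, self.values.T)
        if mode == "ordered":
            return self.values
        raise ValueError(f"unknown symmetrization {mode!r}")


@dataclass
class BlockStat:
    pair_count: int
    fraction_below: float  # percent


@dataclass
class BlockStatistics:
    classes: dict[str, BlockStat] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def fraction(self, name: str) -> float:
        return self.classes[name].fraction_below

    def to_dict(self) -> dict:
        return {
            "classes": {k: {"pair_count": v.pair_count,
                            "fraction_below": v.fraction_below}
                        for k, v in self.classes.items()},
            "notes": list(self.notes),
        }


@dataclass
class ReliabilityReport:
    stability: str   # 'S' or 'U'
    grade: str       # 'R', 'PR' or 'U'
    blocks: BlockStatistics
    notes: str = ""

    def to_dict(self) -> dict:
        return {"stability": self.stability, "grade": self.grade,
                "blocks": self.blocks.to_dict(), "notes": self.notes}


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _matrix_from_nested(data, key: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise PaeFormatError(f"key {key!r}: expected a square nested list, got shape {arr.shape}")
    return arr


def _matrix_from_triplets(obj: dict) -> np.ndarray:
    r1 = np.asarray(obj["residue1"], dtype=int)
    r2 = np.asarray(obj["residue2"], dtype=int)
    d = np.asarray(obj["distance"], dtype=float)
    if not (len(r1) == len(r2) == len(d)):
        raise PaeFormatError("residue1/residue2/distance arrays have mismatched lengths")
    n = int(max(r1.max(), r2.max()))
    if len(d) != n * n:
        raise PaeFormatError(f"triplet dialect: {len(d)} entries cannot fill a {n}x{n} matrix")
    mat = np.full((n, n), np.nan)
    mat[r1 - 1, r2 - 1] = d
    if np.any(np.isnan(mat)):
        raise PaeFormatError("triplet dialect leaves unfilled matrix entries")
    return mat


def read_pae(path: str | Path,
             segmentation: list[tuple[str, int]] | None = None) -> PaeMatrix:
    """Read a PAE JSON file in either supported dialect.

    Dialects: a dict (optionally wrapped in a one-element list) holding a
    nested L x L list under ``pae`` or ``predicted_aligned_error``, or the
    flat triplet form with parallel ``residue1``/``residue2``/``distance``
    arrays.  ``segmentation`` defaults to a single chain 'A' spanning all
    residues; callers pairing the matrix with a structure should pass the
    structure's segmentation.
    """
    with open(path) as handle:
        data = json.load(handle)
    if isinstance(data, list):
        if len(data) >= 1 and isinstance(data[0], dict):
            data = data[0]
        else:
            raise PaeDialectError("top-level JSON list does not wrap a PAE object")
    if not isinstance(data, dict):
        raise PaeDialectError(f"unexpected top-level JSON type {type(data).__name__}")

    if "pae" in data:
        mat = _matrix_from_nested(data["pae"], "pae")
    elif "predicted_aligned_error" in data:
        mat = _matrix_from_nested(data["predicted_aligned_error"], "predicted_aligned_error")
    elif {"residue1", "residue2", "distance"} <= set(data):
        mat = _matrix_from_triplets(data)
    else:
        raise PaeDialectError(
            f"unrecognized PAE dialect; keys found: {sorted(data.keys())}")

    if segmentation is None:
        segmentation = [("A", mat.shape[0])]
    return PaeMatrix(mat, segmentation)


# ---------------------------------------------------------------------------
# Block statistics
# ---------------------------------------------------------------------------

def _domain_indices(pae: PaeMatrix, domains: DomainMap,
                    residue_numbers: list[np.ndarray] | None
                    ) -> list[dict[str, np.ndarray]]:
    """Per chain, flat matrix indices of each mapped BTB/CTD residue."""
    if residue_numbers is None:
        residue_numbers = [np.arange(1, n + 1) for _, n in pae.segmentation]
    if len(residue_numbers) != pae.n_chains:
        raise PaeFormatError("residue_numbers does not match segmentation")
    out = []
    offset = 0
    for (cid, n), numbers in zip(pae.segmentation, residue_numbers):
        if len(numbers) != n:
            raise PaeFormatError(f"chain {cid}: {len(numbers)} residue numbers for {n} residues")
        per_domain: dict[str, list[int]] = {"BTB": [], "CTD": []}
        for local, num in enumerate(numbers):
            name = domains.domain_of(int(num))
            if name in per_domain:
                per_domain[name].append(offset + local)
        out.append({k: np.array(v, dtype=int) for k, v in per_domain.items()})
        offset += n
    return out


def adjacent_chain_pairs(n_chains: int, mode: str,
                         chain_order: list[int] | None = None) -> list[tuple[int, int]]:
    """Unordered chain-index pairs pooled by the inter blocks.

    ``cyclic`` links ring neighbours under ``chain_order`` (default: file
    order); ``all_pairs`` links every distinct pair.
    """
    if mode == "all_pairs" or n_chains == 2:
        return list(itertools.combinations(range(n_chains), 2))
    order = list(chain_order) if chain_order is not None else list(range(n_chains))
    pairs = set()
    for k in range(n_chains):
        a, b = order[k], order[(k + 1) % n_chains]
        pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def block_fractions(pae: PaeMatrix, domains: DomainMap, config: AnalysisConfig,
                    chain_order: list[int] | None = None,
                    residue_numbers: list[np.ndarray] | None = None) -> BlockStatistics:
    """Percentage of residue pairs below the error threshold, per block class.

    Intra classes pool same-chain pairs (diagonal excluded) over all chains;
    inter classes pool pairs from distinct chains restricted by the adjacency
    mode; the cross-domain class pools same-chain BTB-CTD pairs.  Hinge and
    unmapped residues never enter any block.  Counting is strict (< threshold).
    """
    used_domains = [d for d in ("BTB", "CTD") if domains.has(d)]
    if not used_domains:
        raise DomainMapError("domain map contains neither BTB nor CTD")
    per_chain = _domain_indices(pae, domains, residue_numbers)
    S = pae.symmetrized(config.pair_symmetrization)
    ordered = config.pair_symmetrization == "ordered"
    thr = config.pae_threshold
    stats = BlockStatistics()

    def _tally(name: str, below: int, total: int) -> None:
        if total == 0:
            stats.notes.append(f"{name}: zero pairs, class omitted")
            return
        stats.classes[name] = BlockStat(pair_count=total,
                                        fraction_below=100.0 * below / total)

    # intra classes
    for dom in used_domains:
        below = total = 0
        for chain in per_chain:
            idx = chain[dom]
            if len(idx) < 2:
                continue
            sub = S[np.ix_(idx, idx)]
            if ordered:
                mask = ~np.eye(len(idx), dtype=bool)
                vals = sub[mask]
            else:
                iu = np.triu_indices(len(idx), k=1)
                vals = sub[iu]
            below += int(np.count_nonzero(vals < thr))
            total += vals.size
        _tally(f"intra-{dom}", below, total)

    # inter classes
    pairs = adjacent_chain_pairs(pae.n_chains, config.adjacency, chain_order)
    for dom in used_domains:
        below = total = 0
        for a, b in pairs:
            ia, ib = per_chain[a][dom], per_chain[b][dom]
            if len(ia) == 0 or len(ib) == 0:
                continue
            vals = S[np.ix_(ia, ib)].ravel()
            if ordered:
                vals = np.concatenate([vals, S[np.ix_(ib, ia)].ravel()])
            below += int(np.count_nonzero(vals < thr))
            total += vals.size
        _tally(f"inter-{dom}", below, total)

    # cross-domain (same chain, BTB vs CTD): reported, not graded
    if len(used_domains) == 2:
        below = total = 0
        for chain in per_chain:
            ia, ib = chain["BTB"], chain["CTD"]
            if len(ia) == 0 or len(ib) == 0:
                continue
            vals = S[np.ix_(ia, ib)].ravel()
            if ordered:
                vals = np.concatenate([vals, S[np.ix_(ib, ia)].ravel()])
            below += int(np.count_nonzero(vals < thr))
            total += vals.size
        _tally("cross-domain", below, total)

    return stats


def classify_reliability(blocks: BlockStatistics, config: AnalysisConfig) -> ReliabilityReport:
    """Grade a block-statistics table: R, PR or U (with S/U stability).

    R requires every graded block strictly above ``reliable_percent``; PR
    requires all intra blocks above ``reliable_percent`` and every inter
    block above ``partial_percent``; anything else is U.
    """
    graded = {k: v.fraction_below for k, v in blocks.classes.items() if k in GRADED_CLASSES}
    if not graded:
        raise DomainMapError("no graded block classes present")
    intra = {k: v for k, v in graded.items() if k.startswith("intra")}
    inter = {k: v for k, v in graded.items() if k.startswith("inter")}
    if all(v > config.reliable_percent for v in graded.values()):
        grade = "R"
    elif (intra and all(v > config.reliable_percent for v in intra.values())
          and all(v > config.partial_percent for v in inter.values())):
        grade = "PR"
    else:
        grade = "U"
    stability = "S" if grade in ("R", "PR") else "U"
    notes = (f"thresholds: pae<{config.pae_threshold} A, "
             f"R>{config.reliable_percent}%, PR>{config.partial_percent}%")
    return ReliabilityReport(stability=stability, grade=grade, blocks=blocks, notes=notes)


# ---------------------------------------------------------------------------
# Sub-stoichiometry from chain-pair quadrants
# ---------------------------------------------------------------------------

@dataclass
class SubstoichiometryResult:
    components: list[list[str]]     # chain ids, sorted by size desc then id
    edges: list[tuple[str, str]]
    pair_fractions: dict[tuple[str, str], float]
    label: str

    def to_dict(self) -> dict:
        return {
            "components": self.components,
            "edges": [list(e) for e in self.edges],
            "pair_fractions": {f"{a}-{b}": f for (a, b), f in self.pair_fractions.items()},
            "label": self.label,
        }


def infer_substoichiometry(pae: PaeMatrix, config: AnalysisConfig) -> SubstoichiometryResult:
    """Partition chains into candidate sub-oligomers from low-error quadrants.

    Two chains are linked when the fraction of their inter-chain residue
    pairs below the error threshold exceeds ``reliable_percent``; connected
    components of the resulting graph are the candidate sub-assemblies.
    """
    n = pae.n_chains
    if n < 2:
        raise PaeFormatError("sub-stoichiometry inference needs >= 2 chains")
    S = pae.symmetrized("mean" if config.pair_symmetrization == "ordered"
                        else config.pair_symmetrization)
    slices = pae.chain_slices()
    ids = pae.chain_ids
    thr = config.pae_threshold

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    pair_fractions = {}
    for a, b in itertools.combinations(range(n), 2):
        vals = S[slices[ids[a]], slices[ids[b]]].ravel()
        frac = 100.0 * np.count_nonzero(vals < thr) / vals.size
        pair_fractions[(ids[a], ids[b])] = frac
        if frac > config.reliable_percent:
            edges.append((ids[a], ids[b]))
            parent[find(a)] = find(b)

    groups: dict[int, list[str]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(ids[k])
    components = sorted((sorted(g) for g in groups.values()),
                        key=lambda g: (-len(g), g))
    top = len(components[0])
    if top == n:
        label = oligomer_name(n)
    else:
        label = f"{oligomer_name(top)} propensity"
    return SubstoichiometryResult(components=components, edges=edges,
                                  pair_fractions=pair_fractions, label=label)
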