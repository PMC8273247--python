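"""Conformational-ensemble descriptors for helix/coil peptides.

The descriptors implemented here are the ones used to characterise the
free-state ensembles of ubiquitin-interacting motifs (UIMs): per-residue
helicity and its frame-to-frame persistence, the *alphabeta* collective
variable (similarity of the psi dihedrals to an ideal-helix reference),
the C-alpha radius of gyration, CV-window ensemble extraction, and
subset RMSD against bound-like reference conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .sequences import PeptideSequence

#: index of each backbone atom in the coordinate array
ATOM_INDEX = {name: i for i, name in enumerate(geometry.BACKBONE_ATOMS)}


@dataclass
class ConformerEnsemble:
    """A weighted ensemble of backbone conformers of one peptide.

    Attributes
    ----------
    sequence : PeptideSequence
    dihedrals : array (n_frames, n_res, 2)
        Per-residue (phi, psi), degrees; NaN where undefined (chain termini).
    coords : array (n_frames, n_res, 5, 3)
        Atom order ``N, CA, C, O, CB`` (CB is NaN for glycine).
    weights : array (n_frames,)
        Nonnegative, sum to 1; uniform by default.
    """

    sequence: PeptideSequence
    dihedrals: np.ndarray
    coords: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n_frames, n_res = self.dihedrals.shape[:2]
        if n_res != len(self.sequence):
            raise ValueError("dihedral table does not match sequence length")
        if self.coords.shape != (n_frames, n_res, 5, 3):
            raise ValueError("coordinate array must be (n_frames, n_res, 5, 3)")
        if self.weights is None:
            self.weights = np.full(n_frames, 1.0 / n_frames)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n_frames,):
                raise ValueError("weights must be per-frame")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must not all be zero")
            self.weights = self.weights / total

    @property
    def n_frames(self) -> int:
        return self.dihedrals.shape[0]

    @property
    def n_residues(self) -> int:
        return self.dihedrals.shape[1]

    @property
    def uniform_weights(self) -> bool:
        return bool(np.allclose(self.weights, 1.0 / self.n_frames))

    def ca_coords(self) -> np.ndarray:
        """(n_frames, n_res, 3) C-alpha coordinates."""
        return self.coords[:, :, ATOM_INDEX["CA"], :]

    @classmethod
    def from_dihedrals(cls, sequence: PeptideSequence, dihedrals: np.ndarray,
                       weights: np.ndarray | None = None) -> "ConformerEnsemble":
        """Build coordinates from a dihedral table with ideal geometry."""
        dih = np.asarray(dihedrals, dtype=float)
        coords = geometry.build_backbone_coordinates(dih, sequence.residues)
        return cls(sequence, dih, coords, weights)


@dataclass(frozen=True)
class CVParams:
    """Parameters of the alphabeta collective variable.

    ``psi_ref`` is the reference psi value in radians (default 0.7854 rad,
    the value used when biasing toward helix-like psi angles);
    ``report_mode`` selects the raw sum or its percentage of the number
    of angles.
    """

    psi_ref: float = 0.7854
    report_mode: str = "raw"  # "raw" | "percentage"

    def __post_init__(self) -> None:
        if not np.isfinite(self.psi_ref):
            raise ValueError("psi_ref must be finite")
        if self.report_mode not in ("raw", "percentage"):
            raise ValueError("report_mode must be 'raw' or 'percentage'")


@dataclass(frozen=True)
class HelixAssignmentParams:
    """Dihedral-window helix assignment.

    A residue is helical when (phi, psi) fall inside both windows and the
    residue belongs to a contiguous in-window run of at least ``min_run``
    residues.  This is a dihedral-only surrogate for hydrogen-bond-based
    secondary-structure dictionaries, which cannot be evaluated on
    backbone-dihedral input.
    """

    phi_window: tuple[float, float] = (-100.0, -30.0)
    psi_window: tuple[float, float] = (-77.0, -17.0)
    min_run: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.phi_window, self.psi_window):
            if not lo < hi:
                raise ValueError("dihedral windows must be non-empty intervals")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def assign_helix(frame_dihedrals: np.ndarray,
                 params: HelixAssignmentParams = HelixAssignmentParams()
                 ) -> np.ndarray:
    """Per-residue helix assignment for one frame.

    Termini with undefined phi or psi (NaN) are never helical.
    """
    dih = np.asarray(frame_dihedrals, dtype=float)
    phi, psi = dih[:, 0], dih[:, 1]
    in_win = (np.isfinite(phi) & np.isfinite(psi)
              & (phi >= params.phi_window[0]) & (phi <= params.phi_window[1])
              & (psi >= params.psi_window[0]) & (psi <= params.psi_window[1]))
    return _prune_short_runs(in_win, params.min_run)


def _prune_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True-runs of length >= min_run (1-D boolean mask)."""
    out = np.zeros_like(mask)
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def helix_mask(ens: ConformerEnsemble,
               params: HelixAssignmentParams = HelixAssignmentParams()
               ) -> np.ndarray:
    """(n_frames, n_res) boolean helix assignment for every frame."""
    return np.array([assign_helix(f, params) for f in ens.dihedrals])


def helical_fraction(ens: ConformerEnsemble,
                     params: HelixAssignmentParams = HelixAssignmentParams()
                     ) -> np.ndarray:
    """Weighted per-residue fraction of frames assigned helical."""
    if ens.n_frames < 1:
        raise ValueError("ensemble has no frames")
    mask = helix_mask(ens, params)
    if ens.uniform_weights:  # exact mean avoids 1/n summation round-off
        return mask.mean(axis=0)
    return ens.weights @ mask


def persistence_profile(ens: ConformerEnsemble,
                        params: HelixAssignmentParams = HelixAssignmentParams()
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue helix occupancy and mean helical run length over frames.

    Frames are interpreted as an ordered trajectory: for each residue,
    maximal runs of consecutive helical frames are found and their mean
    length returned (0 where the residue is never helical).  Occupancy is
    identical to :func:`helical_fraction`.  Requires uniform weights —
    persistence is a trajectory-order notion and has no meaning for a
    reweighted ensemble.
    """
    if not ens.uniform_weights:
        raise ValueError("persistence requires an unweighted (trajectory) ensemble")
    mask = helix_mask(ens, params)
    occupancy = mask.mean(axis=0)  # == helical_fraction, bit for bit
    mean_run = np.zeros(ens.n_residues)
    for r in range(ens.n_residues):
        col = mask[:, r]
        runs = []
        i = 0
        while i < len(col):
            if col[i]:
                j = i
                while j < len(col) and col[j]:
                    j += 1
                runs.append(j - i)
                i = j
            else:
                i += 1
        mean_run[r] = np.mean(runs) if runs else 0.0
    return occupancy, mean_run


def alphabeta(psi_radians: np.ndarray, params: CVParams = CVParams()) -> float:
    """Alphabeta CV: sum_i (1 + cos(psi_i - psi_ref)) / 2.

    Measures the similarity of each psi dihedral to the reference value;
    ranges from 0 (all psi anti to the reference) to N (all psi equal to
    the reference).  ``percentage`` mode reports 100 * value / N.
    """
    psi = np.asarray(psi_radians, dtype=float)
    if psi.size < 1:
        raise ValueError("alphabeta needs at least one angle")
    value = float(np.sum(0.5 * (1.0 + np.cos(psi - params.psi_ref))))
    if params.report_mode == "percentage":
        return 100.0 * value / psi.size
    return value


def alphabeta_trajectory(ens: ConformerEnsemble,
                         params: CVParams = CVParams()) -> np.ndarray:
    """Per-frame alphabeta over every defined psi angle (residues 1..n-1)."""
    psi = np.deg2rad(ens.dihedrals[:, :-1, 1])
    vals = np.sum(0.5 * (1.0 + np.cos(psi - params.psi_ref)), axis=1)
    if params.report_mode == "percentage":
        vals = 100.0 * vals / psi.shape[1]
    return vals


def radius_of_gyration_trajectory(ens: ConformerEnsemble) -> np.ndarray:
    """Per-frame C-alpha radius of gyration (A)."""
    return np.array([geometry.radius_of_gyration(f) for f in ens.ca_coords()])


def select_frames_by_cv(ens: ConformerEnsemble, cv_values: np.ndarray,
                        cv_range: tuple[float, float]) -> ConformerEnsemble:
    """Sub-ensemble of frames with lo <= cv <= hi (closed interval).

    Weights are renormalised; frame order is preserved.  An empty
    selection yields a valid zero-frame ensemble.
    """
    cv = np.asarray(cv_values, dtype=float)
    if cv.shape != (ens.n_frames,):
        raise ValueError("cv_values must be per-frame")
    lo, hi = cv_range
    keep = (cv >= lo) & (cv <= hi)
    w = ens.weights[keep]
    if keep.sum() == 0:
        out = replace(ens)
        out.dihedrals = ens.dihedrals[:0]
        out.coords = ens.coords[:0]
        out.weights = np.zeros(0)
        return out
    return ConformerEnsemble(ens.sequence, ens.dihedrals[keep],
                             ens.coords[keep], w)


@dataclass(frozen=True)
class RMSDSubsetSpec:
    """Atom subset used for superposition + RMSD over a motif.

    ``motif_interval`` gives construct residue numbers (inclusive);
    ``backbone_atoms`` are taken for every motif residue and
    ``extra_atoms`` adds single atoms such as the beta carbon of the
    conserved motif alanine.
    """

    motif_interval: tuple[int, int]
    backbone_atoms: tuple[str, ...] = ("N", "CA", "C", "O")
    extra_atoms: tuple[tuple[int, str], ...] = ()

    def atom_list(self) -> list[tuple[int, str]]:
        """Canonical (residue_number, atom) order: ascending residue with
        backbone atoms in N, CA, C, O order, then the extra atoms."""
        order = [a for a in ("N", "CA", "C", "O", "CB") if a in self.backbone_atoms]
        atoms = [(r, a)
                 for r in range(self.motif_interval[0], self.motif_interval[1] + 1)
                 for a in order]
        atoms.extend(self.extra_atoms)
        return atoms


@dataclass(frozen=True)
class ReferenceStructure:
    """A bound-like reference conformation covering an RMSD subset.

    ``coords`` maps (motif residue number, atom name) -> xyz.  For
    references with their own numbering (e.g. an experimental UIM-ubiquitin
    complex), apply the residue mapping before construction.
    """

    label: str
    coords: dict

    def subset_coords(self, spec: RMSDSubsetSpec) -> np.ndarray:
        rows = []
        for key in spec.atom_list():
            if key not in self.coords:
                raise KeyError(
                    f"reference {self.label!r} lacks atom {key[1]} of residue {key[0]}")
            rows.append(self.coords[key])
        return np.asarray(rows, dtype=float)


def ensemble_subset_coords(ens: ConformerEnsemble, spec: RMSDSubsetSpec
                           ) -> np.ndarray:
    """(n_frames, n_atoms, 3) coordinates of the spec'd subset."""
    idx = []
    for resnum, atom in spec.atom_list():
        i = ens.sequence.index_of(resnum)
        if atom not in ATOM_INDEX:
            raise KeyError(f"unknown atom name {atom!r}")
        idx.append((i, ATOM_INDEX[atom]))
    sub = np.stack([ens.coords[:, i, a, :] for i, a in idx], axis=1)
    if not np.all(np.isfinite(sub)):
        for (i, a), col in zip(idx, np.rollaxis(sub, 1)):
            if not np.all(np.isfinite(col)):
                resnum = ens.sequence.first_residue_number + i
                name = geometry.BACKBONE_ATOMS[a]
                raise ValueError(
                    f"atom {name} of residue {resnum} missing from ensemble")
    return sub


def motif_rmsd(ens: ConformerEnsemble, ref: ReferenceStructure,
               spec: RMSDSubsetSpec) -> np.ndarray:
    """Per-frame RMSD (A) to the reference on exactly the spec'd atoms."""
    target = ref.subset_coords(spec)
    frames = ensemble_subset_coords(ens, spec)
    return np.array([geometry.superposed_rmsd(f, target) for f in frames])


def bound_like_fraction(rmsds: np.ndarray, threshold: float = 3.0,
                        weights: np.ndarray | None = None) -> float:
    """Weighted fraction of frames with RMSD <= threshold (A)."""
    r = np.asarray(rmsds, dtype=float)
    if r.size < 1:
        raise ValueError("no RMSD values")
    if weights is None:
        return float(np.mean(r <= threshold))
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w[r <= threshold]) / np.sum(w))


def reference_from_ensemble_frame(ens: ConformerEnsemble, frame: int,
                                  spec: RMSDSubsetSpec,
                                  label: str = "frame") -> ReferenceStructure:
    """Use one ensemble frame as a reference structure over the subset."""
    coords = {}
    for resnum, atom in spec.atom_list():
        i = ens.sequence.index_of(resnum)
        coords[(resnum, atom)] = ens.coords[frame, i, ATOM_INDEX[atom], :].copy()
    return ReferenceStructure(label, coords)
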