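"""Synthetic data with the statistical structure the UIM analyses assume.

Three generators:

* helix/coil conformational ensembles with a prescribed per-residue helix
  probability profile (a cooperative two-state model whose *marginals* are
  honoured exactly), standing in for microsecond-scale MD trajectories;
* backbone chemical shifts built as random-coil values plus
  helicity-weighted full-helix offsets plus Gaussian noise, standing in
  for experimental NMR depositions;
* FASTA sequence databases with planted motif instances, plus the
  composition-preserving per-sequence shuffle used as the randomized null
  of the motif-enrichment test.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .sequences import AMINO_ACIDS, PeptideSequence

HELIX_PHI = -57.0
HELIX_PSI = -47.0
#: phi range of the coil basin (degrees)
COIL_PHI = (-180.0, -40.0)
#: psi is drawn uniformly from the union of these two intervals
COIL_PSI_SEGMENTS = ((60.0, 180.0), (-180.0, -150.0))

#: full-helix secondary-shift offsets (ppm): helix moves CA and C' downfield
#: and CB slightly upfield relative to random coil
DEFAULT_HELIX_OFFSETS = {"CA": 2.8, "CB": -0.5, "C": 1.8}


def load_random_coil_table() -> pd.DataFrame:
    """Packaged random-coil shift table, indexed by one-letter residue."""
    ref = importlib.resources.files("uimtools.data") / "random_coil_shifts.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, comment="#", index_col="residue")
    return table


@dataclass
class HelixProfile:
    """Target per-residue helix probabilities for the ensemble generator.

    ``cooperativity`` is a Zimm-Bragg-like nucleation penalty sigma in
    (0, inf): small sigma makes helical residues cluster into long
    segments, sigma >= 1 makes residues independent.  It redistributes
    segment lengths only; the per-residue marginals always converge to
    ``probabilities``.  ``jitter_sd`` is the Gaussian spread (degrees)
    around the ideal helix dihedrals.
    """

    probabilities: np.ndarray
    cooperativity: float = 0.05
    jitter_sd: float = 8.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("helix probabilities must lie in [0, 1]")
        if self.cooperativity < 0:
            raise ValueError("cooperativity must be nonnegative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    @classmethod
    def flat(cls, n_res: int, p: float, **kw) -> "HelixProfile":
        return cls(np.full(n_res, p), **kw)

    @classmethod
    def with_motif(cls, n_res: int, baseline: float, motif_slice: slice,
                   motif_p: float, **kw) -> "HelixProfile":
        prob = np.full(n_res, baseline)
        prob[motif_slice] = motif_p
        return cls(prob, **kw)


def _sample_states(profile: HelixProfile, n_frames: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample (n_frames, n_res) helix/coil states.

    Heterogeneous first-order Markov chain along the sequence.  The
    adjacent-state correlation rho = max(0, 1 - sigma) controls
    cooperativity; the transition probabilities are solved per position so
    that P(state_i = helix) equals the profile exactly, clamping rho
    wherever the exact solution would leave [0, 1].
    """
    p = profile.probabilities
    n_res = len(p)
    rho = max(0.0, 1.0 - profile.cooperativity)
    states = np.zeros((n_frames, n_res), dtype=bool)
    u = rng.random((n_frames, n_res))
    states[:, 0] = u[:, 0] < p[0]
    for i in range(1, n_res):
        prev_p = p[i - 1]
        if prev_p <= 0.0 or prev_p >= 1.0:
            q1 = q0 = p[i]
        else:
            # q0 >= 0 bounds the usable correlation at this step
            rho_max = min(1.0, p[i] * (1 - prev_p) / (prev_p * (1 - p[i]))) \
                if p[i] < 1.0 else 1.0
            r = min(rho, rho_max)
            q1 = p[i] + r * (1.0 - p[i])
            q0 = (p[i] - prev_p * q1) / (1.0 - prev_p)
        thresh = np.where(states[:, i - 1], q1, q0)
        states[:, i] = u[:, i] < thresh
    return states


def _sample_coil_dihedrals(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) coil-basin (phi, psi): broad polyproline/extended region."""
    phi = rng.uniform(*COIL_PHI, size=n)
    (a0, a1), (b0, b1) = COIL_PSI_SEGMENTS
    len_a, len_b = a1 - a0, b1 - b0
    pick_a = rng.random(n) < len_a / (len_a + len_b)
    psi = np.where(pick_a, rng.uniform(a0, a1, size=n), rng.uniform(b0, b1, size=n))
    return np.column_stack([phi, psi])


def generate_helix_coil_ensemble(seq: PeptideSequence, profile: HelixProfile,
                                 n_frames: int, seed: int) -> ConformerEnsemble:
    """Sample a two-state helix/coil ensemble with ideal backbone geometry.

    Helical residues draw (phi, psi) from Gaussians centred on the ideal
    alpha-helix (-57, -47) with ``profile.jitter_sd``; coil residues draw
    uniformly from a broad coil basin.  Marginal helix frequencies converge
    to ``profile.probabilities``.  Deterministic under ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_res = len(seq)
    if len(profile.probabilities) != n_res:
        raise ValueError(
            f"profile length {len(profile.probabilities)} != sequence length {n_res}")
    rng = np.random.default_rng(seed)
    states = _sample_states(profile, n_frames, rng)

    dih = np.empty((n_frames, n_res, 2))
    helix_n = int(states.sum())
    dih[states] = np.column_stack([
        rng.normal(HELIX_PHI, profile.jitter_sd, helix_n),
        rng.normal(HELIX_PSI, profile.jitter_sd, helix_n)])
    coil = ~states
    dih[coil] = _sample_coil_dihedrals(int(coil.sum()), rng)
    # wrap into (-180, 180]
    dih = -((-dih + 180.0) % 360.0 - 180.0)
    dih[:, 0, 0] = np.nan
    dih[:, -1, 1] = np.nan
    return ConformerEnsemble.from_dihedrals(seq, dih)


@dataclass
class ShiftGenerationParams:
    """Forward model for synthetic chemical shifts.

    delta(i, nucleus) = random_coil(aa_i, nucleus)
                        + f_i * helix_offset(nucleus) + N(0, noise_sd).
    """

    random_coil: pd.DataFrame = field(default_factory=load_random_coil_table)
    helix_offsets: dict = field(default_factory=lambda: dict(DEFAULT_HELIX_OFFSETS))
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_chemical_shifts(seq: PeptideSequence, helix_fraction: np.ndarray,
                             params: ShiftGenerationParams, seed: int):
    """Synthetic per-residue shifts for the nuclei in the offset table.

    Returns a :class:`uimtools.chemshift.ChemicalShiftSet`.  Nuclei whose
    random-coil value is undefined for a residue (CB of glycine, amide
    N/H of proline) are skipped.
    """
    from .chemshift import ChemicalShiftSet  # avoid import cycle

    f = np.asarray(helix_fraction, dtype=float)
    if f.shape != (len(seq),):
        raise ValueError("helix_fraction must be per-residue")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("helix fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (aa, resnum) in enumerate(zip(seq.residues, seq.residue_numbers)):
        if aa not in params.random_coil.index:
            raise KeyError(f"residue type {aa!r} absent from random-coil table")
        for nucleus, offset in params.helix_offsets.items():
            if nucleus not in params.random_coil.columns:
                raise KeyError(f"nucleus {nucleus!r} absent from random-coil table")
            rc = params.random_coil.loc[aa, nucleus]
            if pd.isna(rc):
                continue
            shift = rc + f[i] * offset + rng.normal(0.0, params.noise_sd)
            rows.append((resnum, aa, nucleus, shift))
    df = pd.DataFrame(rows, columns=["residue_number", "residue_type",
                                     "nucleus", "shift_ppm"])
    return ChemicalShiftSet(df, provenance=f"synthetic:{seq.id}:seed={seed}")


def generate_sequence_database(n_seqs: int, length: int,
                               composition: dict | None = None,
                               planted: tuple[str, int] | None = None,
                               seed: int = 0) -> list[tuple[str, str]]:
    """Random protein sequences with optional planted motif instances.

    Background residues are i.i.d. from ``composition`` (uniform over the
    20 amino acids by default).  ``planted = (motif_string, n_planted)``
    overwrites a random window of ``n_planted`` distinct sequences with the
    motif string.  Records are ``(id, sequence)`` with deterministic ids
    ``synth_%05d``.
    """
    if n_seqs < 1 or length < 1:
        raise ValueError("need n_seqs >= 1 and length >= 1")
    if composition is None:
        composition = {aa: 1.0 for aa in AMINO_ACIDS}
    letters = sorted(composition)
    probs = np.array([composition[a] for a in letters], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("composition must be a nonnegative frequency table")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    mat = rng.choice(len(letters), size=(n_seqs, length), p=probs)
    seqs = ["".join(letters[k] for k in row) for row in mat]
    if planted is not None:
        motif, n_planted = planted
        if n_planted > n_seqs:
            raise ValueError("cannot plant into more sequences than exist")
        if len(motif) > length:
            raise ValueError(
                f"planted string (len {len(motif)}) longer than sequences ({length})")
        which = rng.choice(n_seqs, size=n_planted, replace=False)
        offsets = rng.integers(0, length - len(motif) + 1, size=n_planted)
        for idx, off in zip(which, offsets):
            s = seqs[idx]
            seqs[idx] = s[:off] + motif + s[off + len(motif):]
    return [(f"synth_{i:05d}", s) for i, s in enumerate(seqs)]


def shuffle_database(db: list[tuple[str, str]], seed: int) -> list[tuple[str, str]]:
    """Independently residue-shuffle each sequence (composition preserved)."""
    if len(db) == 0:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    out = []
    for sid, s in db:
        chars = np.array(list(s))
        rng.shuffle(chars)
        out.append((sid, "".join(chars)))
    return out
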