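"""File I/O: FASTA databases, multi-model PDB ensembles, TSV tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import geometry
from .ensemble import ATOM_INDEX, ConformerEnsemble, ReferenceStructure, RMSDSubsetSpec
from .sequences import ONE_TO_THREE, THREE_TO_ONE, PeptideSequence


# ---------------------------------------------------------------- FASTA

def write_fasta(db: list[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in db]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------- PDB

def write_ensemble_pdb(ens: ConformerEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame).

    Atoms N/CA/C/O/CB per residue; CB omitted for glycine.
    """
    seq = ens.sequence
    keep = []
    for i, aa in enumerate(seq.residues):
        for a, name in enumerate(geometry.BACKBONE_ATOMS):
            if name == "CB" and aa == "G":
                continue
            keep.append((i, a))
    n_atoms = len(keep)
    template = struc.AtomArray(n_atoms)
    template.chain_id = np.full(n_atoms, "A")
    template.res_id = np.array([seq.first_residue_number + i for i, _ in keep])
    template.res_name = np.array([ONE_TO_THREE[seq.residues[i]] for i, _ in keep])
    template.atom_name = np.array([geometry.BACKBONE_ATOMS[a] for _, a in keep])
    template.element = np.array([geometry.BACKBONE_ATOMS[a][0] for _, a in keep])
    template.hetero = np.full(n_atoms, False)
    stack = struc.AtomArrayStack(ens.n_frames, n_atoms)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    coords = np.stack([[ens.coords[f, i, a] for i, a in keep]
                       for f in range(ens.n_frames)])
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble_pdb(path, seq_id: str | None = None) -> ConformerEnsemble:
    """Read a multi-model backbone PDB back into a ConformerEnsemble."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    res_ids = np.unique(stack.res_id)
    first = int(res_ids.min())
    n_res = int(res_ids.max()) - first + 1
    residues = []
    n_frames = stack.stack_depth()
    coords = np.full((n_frames, n_res, 5, 3), np.nan)
    for i, rid in enumerate(range(first, first + n_res)):
        sel = stack.res_id == rid
        if not sel.any():
            raise ValueError(f"residue {rid} missing: numbering not contiguous")
        res_name = stack.res_name[sel][0]
        residues.append(THREE_TO_ONE.get(res_name, "X"))
        for name, a in ATOM_INDEX.items():
            asel = sel & (stack.atom_name == name)
            if asel.any():
                coords[:, i, a, :] = stack.coord[:, asel, :][:, 0, :]
    seq = PeptideSequence(seq_id or "ensemble", "".join(residues), first)
    dihedrals = geometry.backbone_dihedrals(coords)
    return ConformerEnsemble(seq, dihedrals, coords)


def read_reference_pdb(path, spec: RMSDSubsetSpec, refmap=None,
                       label: str | None = None) -> ReferenceStructure:
    """Read a single-model reference PDB covering an RMSD subset.

    ``refmap`` maps reference residue numbers onto motif residue numbers
    (dict or a two-column TSV ``ref_resnum<TAB>motif_resnum``); identity
    when omitted.
    """
    if refmap is not None and not isinstance(refmap, dict):
        table = pd.read_csv(refmap, sep="\t", comment="#")
        refmap = dict(zip(table.iloc[:, 0].astype(int),
                          table.iloc[:, 1].astype(int)))
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    coords = {}
    for atom_i in range(arr.array_length()):
        ref_rn = int(arr.res_id[atom_i])
        motif_rn = refmap.get(ref_rn) if refmap is not None else ref_rn
        if motif_rn is None:
            continue
        coords[(motif_rn, str(arr.atom_name[atom_i]))] = arr.coord[atom_i].copy()
    ref = ReferenceStructure(label or str(path), coords)
    ref.subset_coords(spec)  # validates coverage, raises on missing atoms
    return ref


# ---------------------------------------------------------------- TSV

def write_dihedral_table(ens: ConformerEnsemble, path) -> None:
    """frame / residue_number / phi_deg / psi_deg, tab-separated."""
    rows = []
    for f in range(ens.n_frames):
        for i, rn in enumerate(ens.sequence.residue_numbers):
            rows.append((f, rn, ens.dihedrals[f, i, 0], ens.dihedrals[f, i, 1]))
    pd.DataFrame(rows, columns=["frame", "residue_number", "phi_deg", "psi_deg"]) \
        .to_csv(path, sep="\t", index=False, na_rep="nan")


def read_dihedral_table(path, seq: PeptideSequence) -> ConformerEnsemble:
    df = pd.read_csv(path, sep="\t", comment="#")
    frames = np.sort(df["frame"].unique())
    n_res = len(seq)
    dih = np.full((len(frames), n_res, 2), np.nan)
    for k, f in enumerate(frames):
        sub = df[df.frame == f].sort_values("residue_number")
        if len(sub) != n_res:
            raise ValueError(f"frame {f} has {len(sub)} residues, expected {n_res}")
        dih[k, :, 0] = sub["phi_deg"].to_numpy()
        dih[k, :, 1] = sub["psi_deg"].to_numpy()
    return ConformerEnsemble.from_dihedrals(seq, dih)


def write_shift_table(shifts, path) -> None:
    shifts.entries.to_csv(path, sep="\t", index=False)
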