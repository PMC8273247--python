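"""Chemical-shift analysis: ensemble agreement and helix populations.

Two independent questions are answered from backbone chemical shifts:

1. how well a set of back-calculated shifts matches an experimental set
   (reduced chi-square, normalised by the per-nucleus variance of the
   shift predictor and by the number of shifts compared);
2. how helical each residue is in solution.  The per-residue helix
   population is estimated from the C-alpha / C-beta secondary shifts
   (observed minus random coil): helix shifts CA downfield and CB
   upfield, so f = (dCA - dCB) / (offset_CA - offset_CB), clipped to
   [0, 1] and smoothed with a short window.  This is a deliberately
   simple secondary-shift estimator, not a re-implementation of trained
   predictors such as d2D; classification of a motif as helical
   (mean population > 0.3) or disordered (< 0.1) uses the same decision
   thresholds regardless of estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import THREE_TO_ONE
from .synthetic import DEFAULT_HELIX_OFFSETS, load_random_coil_table

#: nuclei understood by this module (NMR-STAR atom ids mapped onto them)
SUPPORTED_NUCLEI = ("CA", "CB", "C", "N", "H", "HA")

#: default per-nucleus predictor standard deviations (ppm)
DEFAULT_PREDICTOR_SIGMA = {
    "CA": 0.9, "CB": 1.1, "C": 1.1, "N": 2.5, "H": 0.5, "HA": 0.3,
}

_ATOM_ALIASES = {"HN": "H", "CO": "C", "C'": "C"}


class ShiftParseError(ValueError):
    """Malformed or inconsistent chemical-shift input."""


@dataclass
class ChemicalShiftSet:
    """Per-residue, per-nucleus shift values in ppm.

    ``entries`` is a DataFrame with columns ``residue_number``,
    ``residue_type`` (one-letter), ``nucleus``, ``shift_ppm``; at most one
    entry per (residue, nucleus).
    """

    entries: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        need = {"residue_number", "residue_type", "nucleus", "shift_ppm"}
        missing = need - set(self.entries.columns)
        if missing:
            raise ShiftParseError(f"shift table lacks columns {sorted(missing)}")
        e = self.entries.reset_index(drop=True)
        e["residue_number"] = pd.to_numeric(e["residue_number"]).astype("int64")
        e["shift_ppm"] = pd.to_numeric(e["shift_ppm"]).astype(float)
        if not np.all(np.isfinite(e["shift_ppm"])):
            raise ShiftParseError("non-finite shift values")
        dup = e.duplicated(subset=["residue_number", "nucleus"])
        if dup.any():
            row = e[dup].iloc[0]
            raise ShiftParseError(
                f"duplicate entry for residue {row.residue_number} "
                f"nucleus {row.nucleus}")
        types = e.groupby("residue_number")["residue_type"].nunique()
        if (types > 1).any():
            bad = int(types[types > 1].index[0])
            raise ShiftParseError(f"conflicting residue types at residue {bad}")
        self.entries = e

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.sort(self.entries["residue_number"].unique())

    def value(self, residue_number: int, nucleus: str) -> float:
        sel = self.entries[(self.entries.residue_number == residue_number)
                           & (self.entries.nucleus == nucleus)]
        if len(sel) == 0:
            raise KeyError((residue_number, nucleus))
        return float(sel.iloc[0].shift_ppm)

    def pivot(self) -> pd.DataFrame:
        """residues x nuclei wide table (NaN where unobserved)."""
        return self.entries.pivot(index="residue_number", columns="nucleus",
                                  values="shift_ppm")

    def residue_types(self) -> pd.Series:
        return (self.entries.drop_duplicates("residue_number")
                .set_index("residue_number")["residue_type"].sort_index())


def read_shift_table(path, provenance: str | None = None) -> ChemicalShiftSet:
    """Read the simple tab-separated shift dialect.

    Columns: residue_number, residue_type (one- or three-letter), nucleus,
    shift_ppm.  Unsupported nuclei are dropped with a warning column-free.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df["residue_type"] = [
        THREE_TO_ONE.get(t.upper(), t.upper()) for t in df["residue_type"].astype(str)]
    df["nucleus"] = [_ATOM_ALIASES.get(n.upper(), n.upper()) for n in df["nucleus"]]
    df = df[df["nucleus"].isin(SUPPORTED_NUCLEI)].reset_index(drop=True)
    return ChemicalShiftSet(df, provenance or str(path))


def read_nmrstar(path, provenance: str | None = None) -> ChemicalShiftSet:
    """Read an NMR-STAR v3 assigned-chemical-shift loop.

    Residue numbering is taken verbatim from the deposition (``Seq_ID``).
    Entries for unsupported nuclei are dropped; duplicate
    (residue, nucleus) rows raise :class:`ShiftParseError`.
    """
    import gemmi

    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ShiftParseError(f"cannot parse NMR-STAR file {path}: {exc}") from exc
    cols = ["Seq_ID", "Comp_ID", "Atom_ID", "Val"]
    rows = []
    for block in doc:
        tables = [block.find("_Atom_chem_shift.", cols)]
        for item in block:
            frame = item.frame
            if frame is not None:
                tables.append(frame.find("_Atom_chem_shift.", cols))
        for table in tables:
            for row in table:
                rows.append([row[i] for i in range(len(cols))])
    if not rows:
        raise ShiftParseError(f"no assigned-chemical-shift loop found in {path}")
    parsed = []
    for seq_id, comp, atom, val in rows:
        atom = _ATOM_ALIASES.get(atom.upper(), atom.upper())
        if atom not in SUPPORTED_NUCLEI:
            continue
        try:
            resnum = int(seq_id)
            shift = float(val)
        except ValueError as exc:
            raise ShiftParseError(
                f"malformed shift row (Seq_ID={seq_id!r}, Val={val!r})") from exc
        one = THREE_TO_ONE.get(comp.upper(), comp.upper())
        parsed.append((resnum, one, atom, shift))
    df = pd.DataFrame(parsed, columns=["residue_number", "residue_type",
                                       "nucleus", "shift_ppm"])
    return ChemicalShiftSet(df, provenance or str(path))


@dataclass(frozen=True)
class PredictorVariance:
    """Per-nucleus standard deviation (ppm) of the shift predictor."""

    sigma: dict = field(default_factory=lambda: dict(DEFAULT_PREDICTOR_SIGMA))

    def __post_init__(self) -> None:
        for nuc, s in self.sigma.items():
            if not s > 0:
                raise ValueError(f"sigma for {nuc} must be > 0")

    def for_nucleus(self, nucleus: str) -> float:
        if nucleus not in self.sigma:
            raise KeyError(f"no predictor sigma configured for nucleus {nucleus!r}")
        return self.sigma[nucleus]


def reduced_chi2(calc: ChemicalShiftSet, exp: ChemicalShiftSet,
                 sigma: PredictorVariance = PredictorVariance()) -> float:
    """Reduced chi-square between calculated and experimental shifts.

    chi2_red = (1/N) * sum over the N common (residue, nucleus) pairs of
    (delta_calc - delta_exp)^2 / sigma_nucleus^2.  Zero iff all common
    pairs agree exactly; lower is better.
    """
    merged = calc.entries.merge(exp.entries, on=["residue_number", "nucleus"],
                                suffixes=("_calc", "_exp"))
    if len(merged) == 0:
        raise ValueError("no common (residue, nucleus) pairs between the two sets")
    sig = np.array([sigma.for_nucleus(n) for n in merged["nucleus"]])
    dev = (merged["shift_ppm_calc"] - merged["shift_ppm_exp"]).to_numpy()
    return float(np.mean((dev / sig) ** 2))


def secondary_shifts(obs: ChemicalShiftSet,
                     rc_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Secondary shifts: observed minus random coil, residues x nuclei.

    NaN where a shift is unobserved or the random-coil value is undefined
    (CB of glycine).  Raises KeyError for residue types absent from the
    table.
    """
    if rc_table is None:
        rc_table = load_random_coil_table()
    wide = obs.pivot()
    types = obs.residue_types()
    out = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for resnum in wide.index:
        aa = types[resnum]
        if aa not in rc_table.index:
            raise KeyError(f"residue type {aa!r} missing from random-coil table")
        for nucleus in wide.columns:
            rc = rc_table.loc[aa, nucleus] if nucleus in rc_table.columns else np.nan
            out.loc[resnum, nucleus] = wide.loc[resnum, nucleus] - rc
    return out


@dataclass
class SecondaryStructureProfile:
    """Per-residue helix / extended / coil populations (rows sum to 1)."""

    populations: pd.DataFrame  # index residue_number; columns helix/extended/coil
    n_missing: int = 0

    def __post_init__(self) -> None:
        pops = self.populations[["helix", "extended", "coil"]].to_numpy()
        if np.any((pops < -1e-9) | (pops > 1 + 1e-9)):
            raise ValueError("populations outside [0, 1]")
        if not np.allclose(pops.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("populations must sum to 1 per residue")

    @property
    def helix(self) -> pd.Series:
        return self.populations["helix"]


def helix_population(sec: pd.DataFrame,
                     offsets: dict | None = None,
                     smooth_window: int = 3) -> SecondaryStructureProfile:
    """Estimate helix populations from CA/CB secondary shifts.

    f_i = clip((dCA_i - dCB_i) / (offset_CA - offset_CB), 0, 1), smoothed
    by a centred ``smooth_window``-residue mean (1 disables smoothing).
    Residues lacking CA or CB are excluded (counted in ``n_missing``).
    The extended population is fixed at 0 by this estimator; coil is the
    complement of helix.
    """
    if offsets is None:
        offsets = dict(DEFAULT_HELIX_OFFSETS)
    denom = offsets["CA"] - offsets["CB"]
    if denom == 0:
        raise ValueError("offset_CA equals offset_CB: estimator undefined")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    if "CA" not in sec.columns or "CB" not in sec.columns:
        raise ValueError("need CA and CB secondary shifts")
    raw = (sec["CA"] - sec["CB"]) / denom
    have = raw.notna()
    n_missing = int((~have).sum())
    raw = raw[have].clip(0.0, 1.0)
    if len(raw) == 0:
        raise ValueError("no residue has both CA and CB shifts")
    half = smooth_window // 2
    smoothed = {}
    resnums = raw.index.to_numpy()
    for rn in resnums:
        sel = raw[(raw.index >= rn - half) & (raw.index <= rn + half)]
        smoothed[rn] = float(sel.mean())
    helix = pd.Series(smoothed).clip(0.0, 1.0)
    pops = pd.DataFrame({"helix": helix, "extended": 0.0, "coil": 1.0 - helix})
    pops.index.name = "residue_number"
    return SecondaryStructureProfile(pops, n_missing=n_missing)


@dataclass(frozen=True)
class ClassificationResult:
    """Helix-population class of a motif window.

    ``helical`` when the mean helix population over motif residues with
    data exceeds ``hi``; ``disordered`` below ``lo``; otherwise
    ``intermediate`` (boundary values inclusive-intermediate, matching
    the strict inequalities of the thresholds).
    """

    motif_label: str
    mean_helix_population: float
    classification: str
    n_residues_with_data: int
    estimator: str = "ca-cb-secondary-shift-surrogate"


def classify_motif(profile: SecondaryStructureProfile,
                   motif_interval: tuple[int, int],
                   hi: float = 0.3, lo: float = 0.1,
                   label: str | None = None) -> ClassificationResult:
    """Classify a motif window as helical / intermediate / disordered."""
    start, stop = motif_interval
    helix = profile.helix
    sel = helix[(helix.index >= start) & (helix.index <= stop)]
    if len(sel) == 0:
        raise ValueError(
            f"no residue in {start}-{stop} has helix-population data")
    p = float(sel.mean())
    if p > hi:
        cls = "helical"
    elif p < lo:
        cls = "disordered"
    else:
        cls = "intermediate"
    return ClassificationResult(label or f"{start}-{stop}", p, cls, len(sel))
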