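"""High-level report builders used by the command-line interface.

Each function returns a plain dict (JSON-serialisable) that embeds the
resolved configuration and every seed used, so a report can be
regenerated from itself.
"""

from __future__ import annotations

import logging

import numpy as np

from . import chemshift, ensemble as ens_mod, motif as motif_mod

SCHEMA_VERSION = 1

log = logging.getLogger("uimtools")

#: alphabeta windows used to slice heterogeneous ensembles into
#: disordered -> partially helical classes
DEFAULT_CV_RANGES = ((9.0, 17.0), (18.0, 23.0), (24.0, 30.0), (31.0, 34.0))


def parse_interval(text: str) -> tuple[int, int]:
    """Parse '336-350' into (336, 350)."""
    lo, hi = text.split("-")
    lo, hi = int(lo), int(hi)
    if hi < lo:
        raise ValueError(f"interval {text!r} ends before it starts")
    return lo, hi


def run_ensemble_report(ens, motif_interval: tuple[int, int],
                        references: list | None = None,
                        cv_params: ens_mod.CVParams = ens_mod.CVParams(),
                        helix_params: ens_mod.HelixAssignmentParams =
                        ens_mod.HelixAssignmentParams(),
                        cv_ranges: tuple = DEFAULT_CV_RANGES,
                        rmsd_threshold: float = 3.0,
                        extra_rmsd_atoms: tuple = ()) -> dict:
    """Full conformational-ensemble report.

    Per-residue helicity and persistence, the alphabeta distribution (raw
    and percentage), per-CV-window frame counts, and — when references
    are given — per-window bound-like fractions against each reference.
    """
    lo, hi = motif_interval
    seq = ens.sequence
    seq.index_of(lo), seq.index_of(hi)  # validate before compute

    occupancy, mean_run = ens_mod.persistence_profile(ens, helix_params)
    ab = ens_mod.alphabeta_trajectory(ens, cv_params)
    n_psi = ens.n_residues - 1
    spec = ens_mod.RMSDSubsetSpec((lo, hi), extra_atoms=tuple(extra_rmsd_atoms))

    windows = []
    for rlo, rhi in cv_ranges:
        sub = ens_mod.select_frames_by_cv(ens, ab, (rlo, rhi))
        entry = {"range": [rlo, rhi], "n_frames": sub.n_frames,
                 "bound_like_fraction": {}}
        if sub.n_frames == 0:
            log.info("alphabeta window %s-%s selected 0 frames", rlo, rhi)
        for ref in references or []:
            if sub.n_frames == 0:
                entry["bound_like_fraction"][ref.label] = None
                continue
            rmsds = ens_mod.motif_rmsd(sub, ref, spec)
            entry["bound_like_fraction"][ref.label] = ens_mod.bound_like_fraction(
                rmsds, rmsd_threshold, sub.weights)
        windows.append(entry)

    report = {
        "schema_version": SCHEMA_VERSION,
        "sequence": {"id": seq.id, "residues": seq.residues,
                     "first_residue_number": seq.first_residue_number},
        "config": {
            "motif_interval": list(motif_interval),
            "psi_ref_rad": cv_params.psi_ref,
            "phi_window": list(helix_params.phi_window),
            "psi_window": list(helix_params.psi_window),
            "min_run": helix_params.min_run,
            "cv_ranges": [list(r) for r in cv_ranges],
            "rmsd_threshold_A": rmsd_threshold,
            "rmsd_subset_atoms": [list(a) for a in spec.atom_list()],
        },
        "n_frames": ens.n_frames,
        "per_residue": {
            "residue_number": [int(r) for r in seq.residue_numbers],
            "helicity": [float(x) for x in occupancy],
            "mean_helical_run_frames": [float(x) for x in mean_run],
        },
        "alphabeta": {
            "n_angles": n_psi,
            "mean_raw": float(ab.mean()),
            "mean_percentage": float(100.0 * ab.mean() / n_psi),
            "histogram": _histogram(ab, 0.0, float(n_psi), 28),
        },
        "cv_windows": windows,
    }
    return report


def _histogram(values, lo, hi, bins) -> dict:
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return {"bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts]}


def run_classify(shifts: chemshift.ChemicalShiftSet,
                 motif_intervals: list, hi: float = 0.3, lo: float = 0.1,
                 smooth_window: int = 3) -> dict:
    """Per-residue helix populations plus per-motif classification."""
    sec = chemshift.secondary_shifts(shifts)
    profile = chemshift.helix_population(sec, smooth_window=smooth_window)
    motifs = []
    for interval in motif_intervals:
        res = chemshift.classify_motif(profile, interval, hi=hi, lo=lo)
        motifs.append({
            "motif": res.motif_label,
            "mean_helix_population": res.mean_helix_population,
            "class": res.classification,
            "n_residues_with_data": res.n_residues_with_data,
        })
    return {
        "schema_version": SCHEMA_VERSION,
        "provenance": shifts.provenance,
        "estimator": ("CA-CB secondary-shift surrogate; population classes "
                      "use the 0.3/0.1 mean-helix thresholds"),
        "config": {"hi": hi, "lo": lo, "smooth_window": smooth_window},
        "n_residues_missing_ca_or_cb": profile.n_missing,
        "per_residue": {
            "residue_number": [int(r) for r in profile.populations.index],
            "helix": [float(x) for x in profile.populations["helix"]],
            "coil": [float(x) for x in profile.populations["coil"]],
        },
        "motifs": motifs,
    }


def run_scan(db, pattern: motif_mod.MotifPattern,
             n_shuffles: int = 0, seed: int = 0) -> dict:
    """Scan a database; optionally run the shuffled-null enrichment test."""
    hits = motif_mod.scan(db, pattern)
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": {"pattern": pattern.notation, "n_shuffles": n_shuffles,
                   "seed": seed},
        "n_sequences": len(db),
        "n_hits": len(hits),
        "n_sequences_with_hit": motif_mod.hit_sequence_count(hits),
        "hits": [{"seq_id": h.seq_id, "start": h.start, "end": h.end,
                  "match": h.match} for h in hits],
    }
    if n_shuffles >= 1:
        enr = motif_mod.enrichment(db, pattern, n_shuffles, seed)
        report["enrichment"] = {
            "observed": enr.observed,
            "null_mean": float(np.mean(enr.null_counts)),
            "null_max": int(max(enr.null_counts)),
            "enrichment_ratio": enr.enrichment_ratio,
            "p_value": enr.p_value,
            "n_shuffles": n_shuffles,
            "seed": seed,
        }
    return report
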