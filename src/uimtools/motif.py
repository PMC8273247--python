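"""UIM sequence-motif scanning, enrichment and helical-wheel analysis.

The ubiquitin-interacting motif (UIM) consensus is
``X-Ac-Ac-Ac-X-Phi-X-X-Ala-Phi-X-X-Ser-X-X-Ac-X`` (Ac acidic, Phi
hydrophobic).  A refined positional pattern — written in a dash-separated
notation with ``x`` for any residue, ``[..]`` for a residue class,
``(1,2)`` for a one-or-two-residue gap and bare letters for invariants —
selects UIMs likely to be (partially) disordered in the unbound state:

    x-[ED]-[ED]-[ED]-x-[AILVFWMP]-x-x(1,2)-[AVP]-[VPL]-[EDVNTCGPH]-x-S-x-x-[EDTVNCGPH]-x

This module compiles such patterns, scans FASTA-style databases, tests
hit-count enrichment against a composition-preserving per-sequence
shuffle null, and projects motif windows onto an ideal alpha-helical
wheel (100 degrees per residue) for face analysis, including the
location of helix-destabilising beta-branched residues (Val/Ile/Thr).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import AMINO_ACIDS, PeptideSequence
from .synthetic import shuffle_database

#: the refined pattern for UIMs likely to be disordered when unbound
DISORDERED_UIM_PATTERN = ("x-[ED]-[ED]-[ED]-x-[AILVFWMP]-x-x(1,2)-[AVP]-[VPL]-"
                          "[EDVNTCGPH]-x-S-x-x-[EDTVNCGPH]-x")
#: the classical UIM consensus in symbolic-class notation
UIM_CONSENSUS_PATTERN = "X-Ac-Ac-Ac-X-Phi-X-X-Ala-Phi-X-X-Ser-X-X-Ac-X"

DEFAULT_HYDROPHOBIC = frozenset("AILMFVW")
ACIDIC = frozenset("DE")
BETA_BRANCHED = frozenset("VIT")

WHEEL_STEP_DEG = 100.0  # azimuthal rotation per residue on an ideal alpha helix


class PatternError(ValueError):
    """Malformed motif notation."""


@dataclass(frozen=True)
class MotifPattern:
    """Compiled positional pattern.

    ``positions`` is a tuple of ``(allowed_set, min_rep, max_rep)``; at
    most one position may have ``max_rep > min_rep`` (the variable gap).
    """

    positions: tuple
    notation: str

    def __post_init__(self) -> None:
        variable = [p for p in self.positions if p[2] > p[1]]
        if len(variable) > 1:
            raise PatternError("at most one variable-repetition position allowed")
        for allowed, lo, hi in self.positions:
            if not allowed or not set(allowed) <= set(AMINO_ACIDS):
                raise PatternError("each position needs a non-empty residue class")
            if not 1 <= lo <= hi:
                raise PatternError("bad repetition bounds")

    @property
    def min_length(self) -> int:
        return sum(lo for _, lo, _ in self.positions)

    @property
    def max_length(self) -> int:
        return sum(hi for _, _, hi in self.positions)

    def match_length_at(self, seq: str, start: int) -> int | None:
        """Match length at 0-based ``start``, or None.

        The shortest expansion of the variable position is tried first;
        a longer expansion is reported only if the shorter fails.
        """
        reps = [lo for _, lo, _ in self.positions]
        var = next((k for k, (_, lo, hi) in enumerate(self.positions) if hi > lo),
                   None)
        options = [reps]
        if var is not None:
            lo, hi = self.positions[var][1], self.positions[var][2]
            for extra in range(lo + 1, hi + 1):
                alt = list(reps)
                alt[var] = extra
                options.append(alt)
        for counts in options:
            pos = start
            ok = True
            for (allowed, _, _), n in zip(self.positions, counts):
                chunk = seq[pos:pos + n]
                if len(chunk) < n or any(c not in allowed for c in chunk):
                    ok = False
                    break
                pos += n
            if ok:
                return pos - start
        return None


_SYMBOLIC = {
    "X": None,           # placeholder; resolved in compile
    "AC": frozenset("DE"),
    "ALA": frozenset("A"),
    "SER": frozenset("S"),
}

_TOKEN_RE = re.compile(r"^(?P<body>x|X|\[[A-Za-z]+\]|[A-Za-zΦ]+?)"
                       r"(?:\((?P<lo>\d+),(?P<hi>\d+)\))?$")


def compile_pattern(notation: str,
                    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC) -> MotifPattern:
    """Compile dash-separated motif notation into a :class:`MotifPattern`.

    Tokens: ``x``/``X`` any residue; ``[ABC]`` residue class; a bare
    letter a literal; symbolic classes ``Ac`` (acidic), ``Phi`` (the
    configurable hydrophobic set), ``Ala``, ``Ser``; an optional
    ``(lo,hi)`` suffix for variable repetition.
    """
    any_set = frozenset(AMINO_ACIDS)
    positions = []
    for k, token in enumerate(notation.strip().split("-")):
        token = token.strip()
        if not token:
            raise PatternError(f"empty token at position {k + 1}")
        m = _TOKEN_RE.match(token)
        if m is None:
            raise PatternError(f"cannot parse token {token!r} at position {k + 1}")
        body = m.group("body")
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if body in ("x", "X"):
            allowed = any_set
        elif body.startswith("["):
            if not body.endswith("]"):
                raise PatternError(f"unbalanced bracket in token {token!r} "
                                   f"at position {k + 1}")
            allowed = frozenset(body[1:-1].upper())
        elif body.upper() in ("PHI", "Φ"):
            allowed = hydrophobic
        elif body.upper() in _SYMBOLIC and _SYMBOLIC[body.upper()] is not None:
            allowed = _SYMBOLIC[body.upper()]
        elif len(body) == 1 and body.upper() in AMINO_ACIDS:
            allowed = frozenset(body.upper())
        else:
            raise PatternError(f"unknown symbol {body!r} at position {k + 1}")
        bad = set(allowed) - set(AMINO_ACIDS)
        if bad:
            raise PatternError(f"non-residue letters {sorted(bad)} in token "
                               f"{token!r} at position {k + 1}")
        positions.append((allowed, lo, hi))
    return MotifPattern(tuple(positions), notation)


@dataclass(frozen=True)
class MotifHit:
    """A pattern match: 1-based inclusive coordinates within one sequence."""

    seq_id: str
    start: int
    end: int
    match: str


def scan(db: list[tuple[str, str]], pattern: MotifPattern) -> list[MotifHit]:
    """All pattern hits in a sequence database.

    Every match start position is reported (overlapping starts allowed);
    at a fixed start the shortest valid expansion of the variable gap is
    the one recorded.  Hits are sorted by (sequence id, start).  Lowercase
    residues are uppercased with a warning.
    """
    hits = []
    for sid, seq in db:
        if seq != seq.upper():
            warnings.warn(f"lowercase residues in {sid!r} uppercased for scanning")
            seq = seq.upper()
        last_start = len(seq) - pattern.min_length
        for start in range(0, last_start + 1):
            length = pattern.match_length_at(seq, start)
            if length is not None:
                hits.append(MotifHit(sid, start + 1, start + length,
                                     seq[start:start + length]))
    hits.sort(key=lambda h: (h.seq_id, h.start))
    return hits


def hit_sequence_count(hits: list[MotifHit]) -> int:
    """Number of distinct sequences carrying at least one hit."""
    return len({h.seq_id for h in hits})


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed hit count against a shuffled-database null."""

    observed: int
    null_counts: tuple
    seed: int

    @property
    def enrichment_ratio(self) -> float:
        mean_null = float(np.mean(self.null_counts))
        if mean_null == 0.0:
            return 0.0 if self.observed == 0 else float("inf")
        return self.observed / mean_null

    @property
    def p_value(self) -> float:
        n = len(self.null_counts)
        ge = sum(1 for c in self.null_counts if c >= self.observed)
        return (1 + ge) / (1 + n)


def enrichment(db: list[tuple[str, str]], pattern: MotifPattern,
               n_shuffles: int, seed: int) -> EnrichmentResult:
    """Empirical enrichment of pattern hits over per-sequence shuffles.

    The null preserves each sequence's amino-acid composition exactly and
    destroys positional structure; ``p = (1 + #{null >= observed}) /
    (1 + n_shuffles)``.  Deterministic under ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = len(scan(db, pattern))
    child_seeds = np.random.SeedSequence(seed).spawn(n_shuffles)
    null = []
    for cs in child_seeds:
        shuffled = shuffle_database(db, np.random.default_rng(cs))
        null.append(len(scan(shuffled, pattern)))
    return EnrichmentResult(observed, tuple(null), seed)


@dataclass(frozen=True)
class WheelProjection:
    """Azimuthal angles of a sequence window on an ideal helical wheel.

    Residue k of the window (1-based) sits at ``(k - 1) * 100`` degrees
    modulo 360 — the projection of an ideal 3.6-residue-per-turn helix
    onto the plane normal to its axis.
    """

    window: PeptideSequence
    angles: dict  # residue_number -> angle in [0, 360)

    def label(self, residue_number: int) -> str:
        return f"{self.window.residue(residue_number)}{residue_number}"


def wheel_projection(window: PeptideSequence) -> WheelProjection:
    """Helical-wheel angles for every residue of ``window``."""
    if len(window) < 2:
        raise ValueError("wheel projection needs a window of >= 2 residues")
    angles = {rn: ((k * WHEEL_STEP_DEG) % 360.0)
              for k, rn in enumerate(window.residue_numbers)}
    return WheelProjection(window, angles)


def angular_distance(a: float, b: float) -> float:
    """Minimum angle between two azimuths on the circle (degrees)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def face_members(wheel: WheelProjection, center: int,
                 half_width: float = 40.0) -> set[int]:
    """Residues within ``half_width`` degrees of ``center`` on the wheel."""
    if center not in wheel.angles:
        raise KeyError(f"residue {center} not in wheel window")
    c = wheel.angles[center]
    return {rn for rn, a in wheel.angles.items()
            if angular_distance(a, c) <= half_width}


def suboptimal_residue_report(window: PeptideSequence,
                              conserved: tuple[int, int],
                              half_width: float = 40.0) -> list[dict]:
    """Locate beta-branched residues (V/I/T) on the motif's helical wheel.

    Beta-branched residues disfavour helix formation; their placement on
    the functional face (the one carrying the conserved motif Ala and
    Ser) or next to the conserved acidic residues is descriptive evidence
    for a UIM that breaks helicity in solution.  ``conserved`` gives the
    construct numbers of the motif's invariant Ala and Ser.  No score is
    computed — the report lists wheel angles and angular distances only.
    """
    ala_rn, ser_rn = conserved
    wheel = wheel_projection(window)
    for rn, expect in ((ala_rn, "A"), (ser_rn, "S")):
        if window.residue(rn) != expect:
            warnings.warn(f"conserved position {rn} is "
                          f"{window.residue(rn)!r}, expected {expect!r}")
    acidic = [rn for rn in window.residue_numbers
              if window.residue(rn) in ACIDIC]
    report = []
    for rn in window.residue_numbers:
        aa = window.residue(rn)
        if aa not in BETA_BRANCHED:
            continue
        angle = wheel.angles[rn]
        d_ala = angular_distance(angle, wheel.angles[ala_rn])
        d_ser = angular_distance(angle, wheel.angles[ser_rn])
        if acidic:
            d_ac, nearest = min((angular_distance(angle, wheel.angles[a]), a)
                                for a in acidic)
        else:
            d_ac, nearest = float("nan"), None
        report.append({
            "residue": wheel.label(rn),
            "residue_number": rn,
            "angle_deg": angle,
            "dist_to_conserved_ala_deg": d_ala,
            "dist_to_conserved_ser_deg": d_ser,
            "on_conserved_face": min(d_ala, d_ser) <= half_width,
            "nearest_acidic": wheel.label(nearest) if nearest else None,
            "dist_to_nearest_acidic_deg": d_ac,
        })
    return report
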