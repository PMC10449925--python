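"""Hexapeptide window scan, P_HAP statistic and solidification classifier.

The predictor works on a simple premise: a protein can be turned into an
underwater adhesive by unfolding it and letting it re-aggregate, provided its
sequence carries enough short segments with high amyloid (steric-zipper)
propensity.  Segment propensity is quantified by a per-hexapeptide energy in
kcal/mol; windows at or below -23 kcal/mol are self-complementary
("high amyloid propensity", HAP).  P_HAP is the fraction of HAP windows among
all scanned windows, and proteins with P_HAP >= 16.77% are predicted to
solidify into glue.

Energies are expected from an external steric-zipper database export; a
clearly-labelled surrogate scorer is provided for offline work and synthetic
studies.  The surrogate does not reproduce database energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._resources import CANONICAL_RESIDUES, residue_scale

HAP_ENERGY_CUTOFF = -23.0  # kcal/mol, inclusive
SOLIDIFICATION_THRESHOLD = 16.77  # percent, inclusive
DEFAULT_WINDOW = 6


class SequenceError(ValueError):
    """Invalid residue content or window bookkeeping."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named, possibly multi-chain amino-acid sequence.

    Chains are one-letter-code strings; windows never cross chain
    boundaries but all chains pool into one P_HAP denominator.
    """

    name: str
    chains: tuple[str, ...]

    def __post_init__(self):
        if not self.chains:
            raise SequenceError(f"{self.name}: at least one chain required")
        object.__setattr__(self, "chains", tuple(c.upper() for c in self.chains))
        for ci, chain in enumerate(self.chains):
            if not chain:
                raise SequenceError(f"{self.name}: chain {ci} is empty")
            for pos, res in enumerate(chain, start=1):
                if res not in CANONICAL_RESIDUES:
                    raise SequenceError(
                        f"{self.name}: non-canonical residue {res!r} at "
                        f"chain {ci}, position {pos}"
                    )

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass(frozen=True)
class SegmentEnergy:
    """One scored window: 0-based chain index, 1-based start, kcal/mol."""

    chain_index: int
    start: int
    window: str
    energy: float


@dataclass(frozen=True)
class PropensityProfile:
    protein: str
    segments: tuple[SegmentEnergy, ...]
    cutoff: float = HAP_ENERGY_CUTOFF
    n_windows: int = 0
    n_hap: int = 0
    phap: float = 0.0

    @property
    def phap_percent(self) -> float:
        return 100.0 * self.phap


@dataclass(frozen=True)
class SolidificationCall:
    protein: str
    phap_percent: float
    threshold_percent: float = SOLIDIFICATION_THRESHOLD
    predicted: bool = False
    observed: bool | None = None


def read_fasta(path: str | Path, name: str | None = None) -> ProteinSequence:
    """Read a (multi-record) FASTA file as one multi-chain protein.

    Every record becomes one chain, in file order.  ``name`` defaults to the
    first record id stripped of any trailing ``_<chain>`` tag.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records")
    if name is None:
        name = records[0].id.rsplit("_", 1)[0]
    return ProteinSequence(name=name, chains=tuple(str(r.seq) for r in records))


def enumerate_windows(
    seq: ProteinSequence, width: int = DEFAULT_WINDOW
) -> list[tuple[int, int, str]]:
    """All ``width``-residue windows of every chain, in scan order.

    Returns (chain_index, start, window) with 1-based starts.  Chains shorter
    than ``width`` contribute no windows and trigger a warning.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out: list[tuple[int, int, str]] = []
    for ci, chain in enumerate(seq.chains):
        if len(chain) < width:
            warnings.warn(
                f"{seq.name}: chain {ci} (length {len(chain)}) is shorter than "
                f"the window width {width} and contributes no windows",
                stacklevel=2,
            )
            continue
        for start in range(1, len(chain) - width + 2):
            out.append((ci, start, chain[start - 1 : start - 1 + width]))
    return out


def surrogate_energy(
    window: str,
    coeffs: tuple[float, float, float] = (-10.0, -2.0, -5.0),
) -> float:
    """Deterministic stand-in segment energy in kcal/mol.

    An affine combination of the window's mean Kyte-Doolittle hydropathy and
    mean Chou-Fasman beta-sheet propensity::

        E = c0 + c_h * mean(hydropathy) + c_b * mean(P_beta)

    The default coefficients put poly-hydrophilic windows well above the
    -23 kcal/mol HAP cutoff and strongly hydrophobic/beta-prone windows below
    it.  This is a surrogate for an external steric-zipper database and makes
    no claim to reproduce its energies.
    """
    window = window.upper()
    kd = residue_scale("kyte-doolittle")
    cf = residue_scale("chou-fasman-beta")
    for res in window:
        if res not in CANONICAL_RESIDUES:
            raise SequenceError(f"unknown residue {res!r} in window {window!r}")
    c0, ch, cb = coeffs
    n = len(window)
    mean_kd = sum(kd[r] for r in window) / n
    mean_cf = sum(cf[r] for r in window) / n
    return c0 + ch * mean_kd + cb * mean_cf


def score_sequence(
    seq: ProteinSequence,
    width: int = DEFAULT_WINDOW,
    coeffs: tuple[float, float, float] = (-10.0, -2.0, -5.0),
) -> list[SegmentEnergy]:
    """Score every window of ``seq`` with the surrogate energy."""
    return [
        SegmentEnergy(ci, start, win, surrogate_energy(win, coeffs))
        for ci, start, win in enumerate_windows(seq, width)
    ]


def load_energy_table(
    path: str | Path,
    seq: ProteinSequence,
    width: int = DEFAULT_WINDOW,
    strict: bool = False,
) -> list[SegmentEnergy]:
    """Load an external per-segment energy table and validate it against ``seq``.

    The file is comma- or tab-delimited with columns
    ``chain, start, window, energy`` (``#`` comments ignored).  Every row's
    window string must equal the sequence substring at (chain, start).
    Missing windows produce a warning (default) or an error (``strict=True``);
    the P_HAP denominator then counts loaded windows only.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"chain", "start", "window", "energy"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")

    expected = {(ci, start): win for ci, start, win in enumerate_windows(seq, width)}
    segments: list[SegmentEnergy] = []
    for i, row in enumerate(df.itertuples(index=False)):
        key = (int(row.chain), int(row.start))
        win = str(row.window).upper()
        if len(win) != width:
            raise SequenceError(
                f"{path} row {i}: window {win!r} is not {width} residues"
            )
        if key not in expected:
            raise SequenceError(
                f"{path} row {i}: no window at chain {key[0]}, start {key[1]}"
            )
        if expected[key] != win:
            raise SequenceError(
                f"{path} row {i}: window {win!r} disagrees with sequence "
                f"{expected[key]!r} at chain {key[0]}, start {key[1]}"
            )
        segments.append(SegmentEnergy(key[0], key[1], win, float(row.energy)))

    loaded = {(s.chain_index, s.start) for s in segments}
    gaps = sorted(set(expected) - loaded)
    if gaps:
        msg = (
            f"{path}: {len(gaps)} of {len(expected)} windows missing "
            f"(first gaps: {gaps[:5]}); P_HAP denominator uses loaded windows only"
        )
        if strict:
            raise SequenceError(msg)
        warnings.warn(msg, stacklevel=2)
    segments.sort(key=lambda s: (s.chain_index, s.start))
    return segments


def compute_phap(
    segments: Sequence[SegmentEnergy],
    cutoff: float = HAP_ENERGY_CUTOFF,
    protein: str = "",
) -> PropensityProfile:
    """P_HAP: fraction of segments with energy <= cutoff (inclusive)."""
    if not segments:
        raise SequenceError("P_HAP undefined for an empty segment list")
    n = len(segments)
    n_hap = sum(1 for s in segments if s.energy <= cutoff)
    return PropensityProfile(
        protein=protein,
        segments=tuple(segments),
        cutoff=cutoff,
        n_windows=n,
        n_hap=n_hap,
        phap=n_hap / n,
    )


def classify_solidification(
    phap_percent: float,
    threshold_percent: float = SOLIDIFICATION_THRESHOLD,
    protein: str = "",
    observed: bool | None = None,
) -> SolidificationCall:
    """Predict glue formation: P_HAP >= threshold (inclusive).

    The inclusive convention keeps the published survey internally
    consistent: the boundary protein sits exactly at the threshold and is
    observed to solidify.
    """
    if not 0.0 <= phap_percent <= 100.0:
        raise ValueError(f"phap_percent {phap_percent} outside [0, 100]")
    return SolidificationCall(
        protein=protein,
        phap_percent=phap_percent,
        threshold_percent=threshold_percent,
        predicted=phap_percent >= threshold_percent,
        observed=observed,
    )


def evaluate_table1(
    fixture: pd.DataFrame | None = None,
    threshold_percent: float = SOLIDIFICATION_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Classify the packaged 18-protein survey and summarise concordance.

    Returns the per-protein table (with ``predicted`` and ``concordant``
    columns) and a summary dict with confusion counts.
    """
    if fixture is None:
        from ._resources import table1_fixture

        fixture = table1_fixture()
    if len(fixture) != 18:
        raise ValueError(f"expected the 18-protein survey, got {len(fixture)} rows")
    df = fixture.copy()
    calls = [
        classify_solidification(
            row.phap_percent, threshold_percent, protein=row.protein,
            observed=bool(row.solidifies),
        )
        for row in df.itertuples(index=False)
    ]
    df["predicted"] = [c.predicted for c in calls]
    df["concordant"] = df["predicted"] == df["solidifies"]
    tp = int(((df.predicted) & (df.solidifies)).sum())
    tn = int((~df.predicted & ~df.solidifies).sum())
    fp = int((df.predicted & ~df.solidifies).sum())
    fn = int((~df.predicted & df.solidifies).sum())
    summary = {
        "threshold_percent": threshold_percent,
        "n_proteins": len(df),
        "n_predicted_solidifying": int(df.predicted.sum()),
        "n_concordant": int(df.concordant.sum()),
        "true_positive": tp,
        "true_negative": tn,
        "false_positive": fp,
        "false_negative": fn,
    }
    return df, summary
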