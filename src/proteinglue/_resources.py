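"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

#: Molarity of pure water, mol/L (1000 g/L / 18.0 g/mol convention; this is
#: the constant consistent with the 70% volume <-> 38.9 mol/L calibration).
WATER_MOLARITY = 55.56

AVOGADRO = 6.02214076e23

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

FULL_NAME_TO_ONE = {
    "ALANINE": "A", "ARGININE": "R", "ASPARAGINE": "N", "ASPARTATE": "D",
    "ASPARTIC ACID": "D", "CYSTEINE": "C", "GLUTAMINE": "Q", "GLUTAMATE": "E",
    "GLUTAMIC ACID": "E", "GLYCINE": "G", "HISTIDINE": "H", "ISOLEUCINE": "I",
    "LEUCINE": "L", "LYSINE": "K", "METHIONINE": "M", "PHENYLALANINE": "F",
    "PROLINE": "P", "SERINE": "S", "THREONINE": "T", "TRYPTOPHAN": "W",
    "TYROSINE": "Y", "VALINE": "V",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("proteinglue.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=None)
def residue_scale(name: str = "kyte-doolittle") -> dict[str, float]:
    """Return a per-residue scale as a dict keyed by one-letter code.

    Shipped scales: ``kyte-doolittle`` (hydropathy) and ``chou-fasman-beta``
    (beta-sheet conformational propensity).
    """
    files = {
        "kyte-doolittle": "kyte_doolittle.csv",
        "chou-fasman-beta": "chou_fasman_beta.csv",
    }
    try:
        fname = files[name]
    except KeyError:
        raise ValueError(f"unknown residue scale {name!r}; choose from {sorted(files)}")
    df = _read(fname)
    return dict(zip(df["residue"], df["value"].astype(float)))


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    """van der Waals radii in nm keyed by element symbol."""
    df = _read("vdw_radii.csv")
    return dict(zip(df["element"], df["radius_nm"].astype(float)))


def table1_fixture() -> pd.DataFrame:
    """The packaged 18-protein solidification survey.

    Columns: ``index``, ``protein``, ``phap_percent``, ``solidifies``
    (boolean after parsing).
    """
    df = _read("table1.csv")
    df["solidifies"] = df["solidifies"].str.strip().str.lower().map(
        {"yes": True, "no": False}
    )
    if df["solidifies"].isna().any():
        raise ValueError("table1 fixture contains unparseable solidifies entries")
    return df
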