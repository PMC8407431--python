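"""Per-protein physicochemical indices computed from first principles.

Implements the bulk proteome descriptors used to compare viral proteomes
between oceanic regions: amino-acid composition, GRAVY hydropathy (mean
Kyte-Doolittle value per residue), average molecular weight, and the
isoelectric point under a Henderson-Hasselbalch charge model.

All functions operate on sanitized sequences over the 20 canonical one-letter
amino-acid codes (see :mod:`cryoviromics.io` for sanitization rules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, ProteinRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "EMBOSS_PKA",
    "PKaSet",
    "aa_composition",
    "gravy",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "summarize_proteome",
    "region_summary",
    "lysine_arginine_ratio",
]

#: Kyte-Doolittle hydropathy scale; positive = hydrophobic, range [-4.5, 4.5].
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Average (isotope-abundance weighted) residue masses in Daltons.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Mass of one water molecule (Da), added once per chain.
WATER_MASS: float = 18.0153


@dataclass(frozen=True)
class PKaSet:
    """A named set of pKa values for the ionizable groups of a protein.

    Side chains of D, E, C, Y (acidic) and H, K, R (basic) plus the two
    termini. Cysteines are treated as free thiols (no disulfide correction).
    """

    name: str
    n_term: float
    c_term: float
    side_chains: Mapping[str, float]  # D E C Y H K R

    @property
    def acidic(self) -> tuple[tuple[str, float], ...]:
        return tuple((aa, self.side_chains[aa]) for aa in "DECY")

    @property
    def basic(self) -> tuple[tuple[str, float], ...]:
        return tuple((aa, self.side_chains[aa]) for aa in "HKR")


#: EMBOSS default pKa set (the package default; selectable per call).
EMBOSS_PKA = PKaSet(
    name="EMBOSS",
    n_term=8.6,
    c_term=3.6,
    side_chains={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5},
)

# -- fast byte-level encoding ------------------------------------------------

_AA_BYTES = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)
_CODE_LUT = np.full(256, -1, dtype=np.int16)
_CODE_LUT[_AA_BYTES] = np.arange(20)
_KD_VECTOR = np.array([KYTE_DOOLITTLE[a] for a in AA_ALPHABET])
_MASS_VECTOR = np.array([AVERAGE_RESIDUE_MASS[a] for a in AA_ALPHABET])


def _encode(sequence: str) -> np.ndarray:
    """Map a canonical sequence to integer codes 0..19 (A..Y alphabetical)."""
    if not sequence:
        raise ValueError("empty sequence")
    codes = _CODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in sequence if c not in KYTE_DOOLITTLE})
        raise ValueError(f"non-canonical residues in sequence: {bad}")
    return codes


def count_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Residue count matrix, one row per sequence, columns in A..Y order."""
    if len(sequences) == 0:
        return np.zeros((0, 20), dtype=np.int64)
    joined = "".join(sequences)
    codes = _encode(joined)
    lengths = np.fromiter((len(s) for s in sequences), dtype=np.int64, count=len(sequences))
    if lengths.min() == 0:
        raise ValueError("empty sequence")
    owner = np.repeat(np.arange(len(sequences), dtype=np.int64), lengths)
    flat = np.bincount(owner * 20 + codes, minlength=len(sequences) * 20)
    return flat.reshape(len(sequences), 20)


# -- scalar indices ----------------------------------------------------------

def aa_composition(sequence: str) -> np.ndarray:
    """Relative amino-acid frequencies as a 20-vector in A..Y alphabetical
    one-letter order (``ACDEFGHIKLMNPQRSTVWY``); sums to 1."""
    codes = _encode(sequence)
    return np.bincount(codes, minlength=20) / codes.size


def gravy(sequence: str) -> float:
    """GRAVY hydropathy index: arithmetic mean Kyte-Doolittle value."""
    codes = _encode(sequence)
    return float(_KD_VECTOR[codes].mean())


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons (residue masses plus one water)."""
    codes = _encode(sequence)
    return float(_MASS_VECTOR[codes].sum() + WATER_MASS)


def net_charge(counts: np.ndarray | str, ph: float, pka: PKaSet = EMBOSS_PKA) -> float:
    """Modeled net charge at a given pH.

    Henderson-Hasselbalch over the N-terminus, C-terminus, and the side
    chains of D, E, C, Y (acidic) and H, K, R (basic).

    Parameters
    ----------
    counts
        Either a canonical sequence or a 20-vector of residue counts in
        A..Y order.
    """
    if isinstance(counts, str):
        counts = np.bincount(_encode(counts), minlength=20)
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    positive = (1.0, pka.n_term)
    charge = positive[0] / (1.0 + 10.0 ** (ph - positive[1]))
    for aa, pk in pka.basic:
        c = counts[idx[aa]]
        if c:
            charge += c / (1.0 + 10.0 ** (ph - pk))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for aa, pk in pka.acidic:
        c = counts[idx[aa]]
        if c:
            charge -= c / (1.0 + 10.0 ** (pk - ph))
    return float(charge)


def isoelectric_point(
    sequence: str | np.ndarray,
    pka: PKaSet = EMBOSS_PKA,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: the pH at which the modeled net charge is zero.

    Solved by bisection on [0, 14] until the bracketing interval is
    narrower than ``tol`` (a |charge| stopping rule alone is unreliable for
    weakly buffered compositions, where the charge curve is nearly flat
    around the root). Results outside [0, 14] are clamped to the boundary
    (only reachable for pathological compositions, e.g. very long
    homopolymers of K/R).
    """
    if isinstance(sequence, str):
        counts = np.bincount(_encode(sequence), minlength=20)
    else:
        counts = np.asarray(sequence)
    lo, hi = 0.0, 14.0
    if net_charge(counts, lo, pka) <= 0:
        return lo
    if net_charge(counts, hi, pka) >= 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- proteome-level summaries ------------------------------------------------

_FREQ_COLUMNS = [f"freq_{aa}" for aa in AA_ALPHABET]


def summarize_proteome(
    records: Iterable[ProteinRecord],
    compute_pi: bool = True,
    pka: PKaSet = EMBOSS_PKA,
) -> pd.DataFrame:
    """One row of physicochemical indices per protein.

    Columns: ``protein_id, region, length, mw, hy`` (+ ``pi`` unless
    ``compute_pi=False``) and the 20 relative-frequency columns
    ``freq_A .. freq_Y``. MW, GRAVY and composition are vectorized over
    residue counts; pI is solved per protein by bisection.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record collection")
    counts = count_matrix([r.sequence for r in records])
    lengths = counts.sum(axis=1)
    out = pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "region": [r.region for r in records],
            "length": lengths,
            "mw": counts @ _MASS_VECTOR + WATER_MASS,
            "hy": (counts @ _KD_VECTOR) / lengths,
        }
    )
    if compute_pi:
        out["pi"] = [isoelectric_point(c, pka=pka) for c in counts]
    freqs = counts / lengths[:, None]
    out[_FREQ_COLUMNS] = freqs
    return out


def region_summary(properties: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean/SD/min/max of each numeric property (long format)."""
    value_cols = [c for c in properties.columns if c not in ("protein_id", "region")]
    rows = []
    for region, sub in properties.groupby("region", sort=True):
        for col in value_cols:
            v = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "region": region,
                    "property": col,
                    "n": v.size,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                    "min": v.min(),
                    "max": v.max(),
                }
            )
    return pd.DataFrame(rows)


def lysine_arginine_ratio(properties: pd.DataFrame) -> pd.DataFrame:
    """Per-region ratio of total lysine to total arginine residue counts.

    A higher K:R ratio is the classic cold-adaptation signature (lysine
    substituting for arginine reduces salt bridges and backbone rigidity).
    Regions with zero arginine counts get a missing ratio.
    """
    k_counts = properties["freq_K"] * properties["length"]
    r_counts = properties["freq_R"] * properties["length"]
    df = pd.DataFrame(
        {
            "region": properties["region"],
            "k_count": k_counts,
            "r_count": r_counts,
        }
    )
    grouped = df.groupby("region", sort=True).sum()
    ratio = grouped["k_count"] / grouped["r_count"]
    ratio[grouped["r_count"] <= 0] = math.nan
    out = grouped.reset_index()
    out["k_to_r_ratio"] = ratio.to_numpy()
    out["k_count"] = out["k_count"].round().astype(np.int64)
    out["r_count"] = out["r_count"].round().astype(np.int64)
    return out
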