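"""Per-residue physicochemical scales used by the CDR3 property summaries.

Each scale maps the 20 standard amino-acid letters to a real value and is
aggregated over a peptide either as a mean of weights, a closed formula
(aliphatic index, net charge), or a fraction (aromaticity).  Literature
sources for each table are recorded in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle hydropathy (GRAVY weights).
KYTE_DOOLITTLE_HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Grantham polarity.
GRANTHAM_POLARITY: dict[str, float] = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

#: Zimmerman bulkiness.
ZIMMERMAN_BULKINESS: dict[str, float] = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

#: Gas-phase basicity (kJ/mol).
GAS_PHASE_BASICITY: dict[str, float] = {
    "A": 206.4, "R": 245.2, "N": 212.8, "D": 208.6, "C": 206.2,
    "Q": 214.2, "E": 215.6, "G": 202.7, "H": 223.7, "I": 210.8,
    "L": 209.6, "K": 221.8, "M": 213.3, "F": 212.1, "P": 214.4,
    "S": 207.6, "T": 211.7, "W": 216.1, "Y": 213.1, "V": 208.7,
}

#: Side-chain acidity indicator (1 for the carboxylate side chains D/E).
ACIDITY_INDICATOR: dict[str, float] = {
    aa: (1.0 if aa in "DE" else 0.0) for aa in AA_LETTERS
}

#: Atchley factors: five factor-analysis descriptors per residue.
ATCHLEY_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

#: Kidera factors: ten dimension-reduction descriptors per residue.
KIDERA_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48),
    "R": (0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93),
    "N": (1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73),
    "D": (0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70),
    "C": (0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10),
    "Q": (-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33),
    "E": (-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12),
    "G": (1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46),
    "H": (-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63),
    "I": (-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78),
    "L": (-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93),
    "K": (-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60),
    "M": (-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27),
    "F": (-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44),
    "P": (2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28),
    "S": (0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23),
    "T": (0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19),
    "W": (0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60),
    "Y": (1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53),
    "V": (-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65),
}

#: EMBOSS side-chain pKa values for the Henderson–Hasselbalch net charge.
EMBOSS_PKA: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = "RKH"
_NEGATIVE = "DECY"

AROMATIC = frozenset("FWY")


@dataclass(frozen=True)
class AAPropertyScale:
    """A named per-residue scale with its aggregation rule."""

    name: str
    weights: Mapping[str, float]
    aggregation: str = "mean"  # mean | formula

    def __post_init__(self) -> None:
        missing = set(AA_LETTERS) - set(self.weights)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")


def mean_weight(seq: str, weights: Mapping[str, float]) -> float:
    """Arithmetic mean of per-residue weights over a peptide."""
    if not seq:
        raise ValueError("empty amino-acid string")
    return sum(weights[aa] for aa in seq) / len(seq)


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle weight)."""
    return mean_weight(seq, KYTE_DOOLITTLE_HYDROPATHY)


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu).

    X are mole percentages of each residue.
    """
    if not seq:
        raise ValueError("empty amino-acid string")
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def aromaticity(seq: str) -> float:
    """Fraction of residues that are F, W or Y."""
    if not seq:
        raise ValueError("empty amino-acid string")
    return sum(1 for aa in seq if aa in AROMATIC) / len(seq)


def net_charge(seq: str, ph: float = 7.4) -> float:
    """Henderson–Hasselbalch net side-chain charge at the given pH.

    Uses the EMBOSS pKa set; N-/C-terminal charges are excluded so the value
    reflects CDR3 side-chain composition only.
    """
    if not seq:
        raise ValueError("empty amino-acid string")
    charge = 0.0
    for aa in seq:
        pka = EMBOSS_PKA.get(aa)
        if pka is None:
            continue
        if aa in _POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        elif aa in _NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


#: Scales keyed by the summary names used across the package.
SCALES: dict[str, AAPropertyScale] = {
    "gravy": AAPropertyScale("gravy", KYTE_DOOLITTLE_HYDROPATHY),
    "polarity": AAPropertyScale("polarity", GRANTHAM_POLARITY),
    "bulkiness": AAPropertyScale("bulkiness", ZIMMERMAN_BULKINESS),
    "basicity": AAPropertyScale("basicity", GAS_PHASE_BASICITY),
    "acidity": AAPropertyScale("acidity", ACIDITY_INDICATOR),
}
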