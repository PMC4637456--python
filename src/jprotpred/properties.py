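"""Physicochemical property table for sequence-order correlation features.

Twelve per-residue properties — hydrophobicity, hydrophilicity, average
accessible surface area, average flexibility, net charge, side-chain
volume, polarity, heat capacity, isoelectric point, transfer free energy
to the surface, van der Waals volume, and side-chain interaction
parameter — taken from published amino-acid index tables (AAindex-style
accessions recorded per column).  Raw index scales are arbitrary, so each
property is z-standardised over the 20 amino acids before use; the
correlation features are therefore invariant to affine rescaling of any
raw column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AMINO_ACIDS, ValidationError

# raw values in alphabetical residue order (A C D E F G H I K L M N P Q R S T V W Y)
_RAW_PROPERTIES: dict[str, dict[str, float]] = {
    # Kyte-Doolittle hydropathy (KYTJ820101)
    "hydrophobicity": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
        3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2])),
    # Hopp-Woods hydrophilicity (HOPT810101)
    "hydrophilicity": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        -0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
        -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5])),
    # Chothia residue accessible surface area in tripeptide (CHOC760101)
    "accessible_surface_area": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        115.0, 225.0, 160.0, 150.0, 135.0, 180.0, 190.0, 75.0, 195.0, 175.0,
        170.0, 200.0, 185.0, 210.0, 145.0, 115.0, 140.0, 255.0, 230.0, 155.0])),
    # Bhaskaran-Ponnuswamy average flexibility (BHAR880101)
    "flexibility": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        0.357, 0.529, 0.463, 0.511, 0.346, 0.493, 0.497, 0.544, 0.323, 0.462,
        0.365, 0.466, 0.295, 0.314, 0.509, 0.507, 0.444, 0.305, 0.420, 0.386])),
    # Klein net charge (KLEP840101)
    "net_charge": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        0.0, 1.0, 0.0, -1.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0,
        0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])),
    # Chothia residue volume (CHOC750101)
    "side_chain_volume": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        88.6, 173.4, 114.1, 111.1, 108.5, 143.8, 138.4, 60.1, 153.2, 166.7,
        166.7, 168.6, 162.9, 189.9, 112.7, 89.0, 116.1, 227.8, 193.6, 140.0])),
    # Grantham polarity (GRAR740102)
    "polarity": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2,
        4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9])),
    # Hutchens heat capacity (HUTJ700101)
    "heat_capacity": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        29.22, 26.37, 38.30, 37.09, 50.70, 44.02, 41.84, 23.71, 59.64, 45.00,
        48.03, 57.10, 69.32, 48.52, 36.13, 32.40, 35.20, 56.92, 51.73, 40.35])),
    # Zimmerman isoelectric point (ZIMJ680104)
    "isoelectric_point": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        6.00, 10.76, 5.41, 2.77, 5.05, 5.65, 3.22, 5.97, 7.59, 6.02,
        5.98, 9.74, 5.74, 5.48, 6.30, 5.68, 5.66, 5.89, 5.66, 5.96])),
    # Bull-Breese surface transfer free energy (BULH740101)
    "transfer_free_energy": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        0.610, 0.690, 0.890, 0.610, 0.360, 0.970, 0.510, 0.810, 0.690, -1.450,
        -1.650, 0.460, -0.660, -1.520, -0.170, 0.420, 0.290, -1.200, -1.430, -0.750])),
    # Fauchere normalized van der Waals volume (FAUJ880103)
    "van_der_waals": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        1.00, 6.13, 2.95, 2.78, 2.43, 3.95, 3.78, 0.00, 4.66, 4.00,
        4.00, 4.77, 4.43, 5.89, 2.72, 1.60, 2.60, 8.08, 6.47, 3.00])),
    # Krigbaum-Rubin side chain interaction parameter (KRIW790101)
    "side_chain_interaction": dict(zip("ARNDCQEGHILKMFPSTWYV", [
        9.25, 10.74, 12.78, 10.93, 4.88, 11.64, 11.89, 11.58, 12.50, 1.97,
        3.03, 12.05, 4.23, 2.83, 7.27, 12.53, 10.81, 5.89, 8.53, 4.18])),
}

_PROPERTY_IDS: dict[str, str] = {
    "hydrophobicity": "KYTJ820101",
    "hydrophilicity": "HOPT810101",
    "accessible_surface_area": "CHOC760101",
    "flexibility": "BHAR880101",
    "net_charge": "KLEP840101",
    "side_chain_volume": "CHOC750101",
    "polarity": "GRAR740102",
    "heat_capacity": "HUTJ700101",
    "isoelectric_point": "ZIMJ680104",
    "transfer_free_energy": "BULH740101",
    "van_der_waals": "FAUJ880103",
    "side_chain_interaction": "KRIW790101",
}

PROPERTY_NAMES: tuple[str, ...] = tuple(_RAW_PROPERTIES)


@dataclass
class PropertyTable:
    """20 x P matrix of per-residue property values.

    Rows follow alphabetical residue order; ``values`` holds the
    z-standardised columns (mean 0, population SD 1 over the 20 residues)
    when constructed via :meth:`default` or :meth:`from_raw`.
    """

    values: np.ndarray
    property_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 20:
            raise ValidationError(
                f"property table must be 20 x P, got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValidationError("property table contains missing values")

    @property
    def n_properties(self) -> int:
        return self.values.shape[1]

    def profile(self, sequence: str) -> np.ndarray:
        """L x P matrix of property values along a sequence."""
        idx = np.fromiter(
            (AMINO_ACIDS.index(aa) for aa in sequence), dtype=int,
            count=len(sequence),
        )
        return self.values[idx]

    @classmethod
    def from_raw(
        cls, raw: np.ndarray, property_ids: tuple[str, ...] = ()
    ) -> "PropertyTable":
        """Z-standardise raw columns over the 20 amino acids."""
        raw = np.asarray(raw, dtype=float)
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0)
        if np.any(sd == 0):
            raise ValidationError("constant property column cannot be standardised")
        return cls(values=(raw - mu) / sd, property_ids=property_ids)

    @classmethod
    def default(cls) -> "PropertyTable":
        """The standard 12-property table, z-standardised."""
        raw = np.column_stack(
            [
                [_RAW_PROPERTIES[name][aa] for aa in AMINO_ACIDS]
                for name in PROPERTY_NAMES
            ]
        )
        return cls.from_raw(
            raw, property_ids=tuple(_PROPERTY_IDS[n] for n in PROPERTY_NAMES)
        )
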