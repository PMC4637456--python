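"""Hybrid feature extraction: SAAC, PseAAC, and PSSM autocovariance.

Every protein is encoded as the concatenation of three blocks:

* **SAAC** (split amino acid composition, 60 values): the 20-letter
  amino-acid frequency vector computed separately over the N-terminal
  ``lnc`` residues, the central segment, and the C-terminal ``lnc``
  residues.  Terminal composition bias carries type information because
  the J-domain and its flanking regions sit near the termini.
* **PseAAC** (12 x ``gamma_max`` values): for each of 12 z-standardised
  physicochemical properties, the lag-gamma autocovariance of the property
  profile along the sequence,

  .. math:: f_{j,\\gamma} = \\frac{1}{L-\\gamma} \\sum_{i=1}^{L-\\gamma}
        (p_{ij} - \\bar p_j)(p_{i+\\gamma,j} - \\bar p_j),

  with :math:`\\bar p_j` the mean of property *j* over the sequence.
* **PSSM-AC** (20 x ``lambda_max`` values): the same autocovariance
  applied column-wise to the sigmoid-normalised PSSM,
  :math:`f(x) = 1/(1+e^{-x})`, capturing local conservation patterns.

With the default parameters (lnc=22, gamma_max=8, lambda_max=5) the
hybrid vector has 60 + 96 + 100 = 256 dimensions.  Feature ordering is
frozen — SAAC parts N/middle/C with residues alphabetical, then PseAAC
property-major with lags ascending, then PSSM-AC column-major with lags
ascending — so selected-feature indices are portable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMINO_ACIDS, ProteinRecord, PSSMProfile, ValidationError
from .properties import PROPERTY_NAMES, PropertyTable

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class FeatureConfig:
    """Parameters of the hybrid feature encoding.

    lnc
        Length of the N- and C-terminal SAAC segments (residues).
    gamma_max
        Largest sequence-order lag of the PseAAC block.
    lambda_max
        Largest lag of the PSSM autocovariance block.
    short_sequence_policy
        What to do when a sequence is shorter than ``2*lnc + 1``:
        ``"error"`` (training default) or ``"thirds"`` (split into three
        near-equal contiguous segments instead; prediction default).
    """

    lnc: int = 22
    gamma_max: int = 8
    lambda_max: int = 5
    short_sequence_policy: str = "error"

    def __post_init__(self) -> None:
        if self.lnc < 1 or self.gamma_max < 1 or self.lambda_max < 1:
            raise ValidationError("lnc, gamma_max, lambda_max must be >= 1")
        if self.short_sequence_policy not in ("error", "thirds"):
            raise ValidationError(
                f"unknown short_sequence_policy {self.short_sequence_policy!r}"
            )

    @property
    def n_features(self) -> int:
        return 60 + 12 * self.gamma_max + 20 * self.lambda_max


def feature_names(config: FeatureConfig) -> list[str]:
    """Stable global feature names, in block order."""
    names = [
        f"saac.{part}.{aa}"
        for part in ("N", "M", "C")
        for aa in AMINO_ACIDS
    ]
    names += [
        f"pseaac.p{j + 1}.g{g}"
        for j in range(12)
        for g in range(1, config.gamma_max + 1)
    ]
    names += [
        f"pssm.{aa}.l{lam}"
        for aa in AMINO_ACIDS
        for lam in range(1, config.lambda_max + 1)
    ]
    return names


def block_index(config: FeatureConfig) -> dict[str, range]:
    """Index spans of the SAAC / PseAAC / PSSM-AC blocks."""
    n_pse = 12 * config.gamma_max
    return {
        "saac": range(0, 60),
        "pseaac": range(60, 60 + n_pse),
        "pssm_ac": range(60 + n_pse, 60 + n_pse + 20 * config.lambda_max),
    }


def _aa_frequencies(segment: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in segment:
        counts[_AA_INDEX[aa]] += 1
    if len(segment):
        counts /= len(segment)
    return counts


def compute_saac(
    sequence: str, lnc: int = 22, policy: str = "error"
) -> np.ndarray:
    """Split amino acid composition over N-terminal / middle / C-terminal.

    Requires ``len(sequence) >= 2*lnc + 1`` so the three segments are
    nonempty and disjoint.  Under ``policy="thirds"`` shorter sequences
    are split into three contiguous near-equal thirds instead.
    """
    L = len(sequence)
    if L >= 2 * lnc + 1:
        parts = (sequence[:lnc], sequence[lnc:L - lnc], sequence[L - lnc:])
    elif policy == "thirds":
        a, b = round(L / 3), round(2 * L / 3)
        parts = (sequence[:a], sequence[a:b], sequence[b:])
    else:
        raise ValidationError(
            f"sequence of length {L} is shorter than 2*lnc+1 = {2 * lnc + 1}; "
            "use short_sequence_policy='thirds' to split into thirds"
        )
    return np.concatenate([_aa_frequencies(p) for p in parts])


def _autocovariance(profile: np.ndarray, max_lag: int) -> np.ndarray:
    """Column-wise lag-1..max_lag autocovariance, column-major ordering.

    Returns a flat vector ``[col0 lag1..K, col1 lag1..K, ...]`` where each
    entry is the mean product of mean-centred values ``lag`` apart, the
    mean taken over the whole column and the sum divided by ``L - lag``.
    """
    L, n_cols = profile.shape
    if L <= max_lag:
        raise ValidationError(
            f"profile of length {L} too short for max lag {max_lag}"
        )
    centred = profile - profile.mean(axis=0)
    out = np.empty((n_cols, max_lag))
    for lag in range(1, max_lag + 1):
        out[:, lag - 1] = (centred[:-lag] * centred[lag:]).sum(axis=0) / (L - lag)
    return out.ravel()


def compute_pseaac(
    sequence: str,
    properties: PropertyTable | None = None,
    gamma_max: int = 8,
) -> np.ndarray:
    """Sequence-order correlation factors over physicochemical profiles.

    One autocovariance value per (property, lag) pair, property-major with
    lags ascending; 12 properties at defaults give a 96-vector.
    """
    if properties is None:
        properties = PropertyTable.default()
    if len(sequence) <= gamma_max:
        raise ValidationError(
            f"sequence of length {len(sequence)} too short for gamma_max "
            f"{gamma_max}"
        )
    return _autocovariance(properties.profile(sequence), gamma_max)


def sigmoid_normalize(pssm: PSSMProfile | np.ndarray) -> np.ndarray:
    """Map PSSM log-odds elementwise into (0, 1) via 1/(1 + e^(-x))."""
    scores = pssm.scores if isinstance(pssm, PSSMProfile) else np.asarray(pssm)
    # expit, written out to keep scipy optional here
    return 1.0 / (1.0 + np.exp(-scores))


def compute_pssm_ac(pssm: PSSMProfile, lambda_max: int = 5) -> np.ndarray:
    """Autocovariance features of the sigmoid-normalised PSSM.

    One value per (residue column, lag), column-major with lags ascending;
    lambda_max=5 gives a 100-vector.  The fallback zero profile normalises
    to a constant 0.5 matrix, so all its features are exactly zero.
    """
    if pssm.length <= lambda_max:
        raise ValidationError(
            f"PSSM of length {pssm.length} too short for lambda_max "
            f"{lambda_max}"
        )
    return _autocovariance(sigmoid_normalize(pssm), lambda_max)


def extract_features(
    record: ProteinRecord,
    config: FeatureConfig | None = None,
    properties: PropertyTable | None = None,
) -> np.ndarray:
    """SAAC | PseAAC | PSSM-AC hybrid feature vector for one record."""
    if config is None:
        config = FeatureConfig()
    if properties is None:
        properties = PropertyTable.default()
    try:
        saac = compute_saac(
            record.sequence, config.lnc, config.short_sequence_policy
        )
        pseaac = compute_pseaac(record.sequence, properties, config.gamma_max)
        pssm = record.pssm
        if pssm is None:
            from .io import zero_pssm

            pssm = zero_pssm(len(record.sequence))
        pssm_ac = compute_pssm_ac(pssm, config.lambda_max)
    except ValidationError as err:
        raise ValidationError(f"record {record.id!r}: {err}") from None
    return np.concatenate([saac, pseaac, pssm_ac])


def write_feature_table(
    path,
    ids: Sequence[str],
    labels: Sequence[str | None],
    X: np.ndarray,
    names: Sequence[str],
) -> None:
    """Export a feature matrix as TSV with id and label columns."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(X), columns=list(names))
    df.insert(0, "label", ["" if v is None else v for v in labels])
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    """Read a TSV feature table; returns (ids, labels, X, names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    names = [c for c in df.columns if c not in ("id", "label")]
    labels = [None if (v != v or v == "") else v for v in df["label"]]
    return list(df["id"]), labels, df[names].to_numpy(dtype=float), names


class HybridFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping protein records to the hybrid feature matrix.

    A stateless scikit-learn transformer: ``transform`` accepts a sequence
    of :class:`~jprotpred.io.ProteinRecord` and returns an
    ``(n_records, n_features)`` array.  ``fit`` only validates parameters,
    so the extractor composes with ``sklearn.pipeline.Pipeline``.

    Parameters
    ----------
    lnc : int, default=22
        Terminal segment length for the SAAC block.
    gamma_max : int, default=8
        Maximum PseAAC lag.
    lambda_max : int, default=5
        Maximum PSSM autocovariance lag.
    short_sequence_policy : {"error", "thirds"}, default="error"
        Handling of sequences shorter than ``2*lnc + 1``.
    """

    def __init__(
        self,
        lnc: int = 22,
        gamma_max: int = 8,
        lambda_max: int = 5,
        short_sequence_policy: str = "error",
    ) -> None:
        self.lnc = lnc
        self.gamma_max = gamma_max
        self.lambda_max = lambda_max
        self.short_sequence_policy = short_sequence_policy

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            lnc=self.lnc,
            gamma_max=self.gamma_max,
            lambda_max=self.lambda_max,
            short_sequence_policy=self.short_sequence_policy,
        )

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "HybridFeatureExtractor":
        config = self._config()
        self.n_features_out_ = config.n_features
        self.feature_names_ = feature_names(config)
        self.properties_ = PropertyTable.default()
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "properties_"):
            self.fit(X)
        config = self._config()
        return np.vstack(
            [extract_features(rec, config, self.properties_) for rec in X]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self._config()), dtype=object)
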