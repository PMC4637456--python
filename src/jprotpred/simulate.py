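"""Synthetic imbalanced 4-class benchmark generator.

Emulates the structure of the curated J-protein benchmark — four classes
with severe imbalance (defaults 63/55/1061/20), class-specific amino-acid
composition biases, optional planted N-terminal motifs, and one synthetic
PSSM per sequence — without any biological content.  Letters are drawn
i.i.d. from a per-class distribution: a mixture ``(1 - b) * baseline +
b * q_c`` where ``q_c`` is a class-specific Dirichlet draw and ``b`` is
``composition_bias``; ``b = 0`` gives identical distributions in every
class (a no-signal null).  Synthetic PSSMs are integer log-odds clipped
to [-6, 8] with class-dependent column means of magnitude
``pssm_signal`` plus noise, so the PSSM-autocovariance code path sees
realistic magnitudes.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io import (
    AMINO_ACIDS,
    LabeledDataset,
    ProteinRecord,
    PSSMProfile,
    ValidationError,
    write_pssm,
)

DEFAULT_CLASS_COUNTS: dict[str, int] = {"I": 63, "II": 55, "III": 1061, "IV": 20}


@dataclass
class SimConfig:
    """Parameters of the synthetic benchmark.

    class_counts
        Samples per class; defaults mirror the real benchmark's imbalance.
    length_range
        Inclusive (min, max) sequence length; the minimum must exceed
        twice the default terminal segment length so feature extraction
        never truncates.
    composition_bias
        Mixing weight in [0, 1] toward a class-specific letter
        distribution; 0 means no compositional signal.
    terminal_motif
        Optional per-class motif planted at the N-terminus.
    pssm_signal
        Magnitude of the class-dependent PSSM column means; 0 means the
        profiles carry no class signal.
    """

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    length_range: tuple[int, int] = (70, 300)
    composition_bias: float = 0.3
    terminal_motif: dict[str, str] | None = None
    pssm_signal: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.class_counts.values()):
            raise ValidationError("class counts must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad length_range {self.length_range}")
        if not (0.0 <= self.composition_bias <= 1.0):
            raise ValidationError("composition_bias must be in [0, 1]")
        if self.terminal_motif:
            for cls, motif in self.terminal_motif.items():
                if set(motif) - set(AMINO_ACIDS):
                    raise ValidationError(f"motif for {cls!r} has bad letters")
                if len(motif) >= lo:
                    raise ValidationError(
                        f"motif for {cls!r} longer than the minimum sequence"
                    )

    def scaled(self, factor: float, min_per_class: int = 2) -> "SimConfig":
        """Shrink every class count by ``factor`` (clamped from below)."""
        counts = {
            cls: max(min_per_class, round(cnt / factor))
            for cls, cnt in self.class_counts.items()
        }
        return replace(self, class_counts=counts)


def simulate_dataset(config: SimConfig | None = None) -> LabeledDataset:
    """Draw the synthetic benchmark: sequences, labels, and PSSM profiles."""
    if config is None:
        config = SimConfig()
    rng = np.random.RandomState(config.seed)
    baseline = np.full(20, 1.0 / 20.0)
    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    for cls in sorted(config.class_counts, key=str):
        q_c = rng.dirichlet(np.full(20, 2.0))
        p_c = (1.0 - config.composition_bias) * baseline \
            + config.composition_bias * q_c
        col_bias = config.pssm_signal * rng.standard_normal(20)
        motif = (config.terminal_motif or {}).get(cls, "")
        for i in range(config.class_counts[cls]):
            length = int(rng.randint(lo, hi + 1))
            letters = rng.choice(list(AMINO_ACIDS), size=length, p=p_c)
            seq = motif + "".join(letters)[len(motif):]
            scores = np.clip(
                np.round(col_bias + 2.0 * rng.standard_normal((length, 20))),
                -6, 8,
            )
            records.append(
                ProteinRecord(
                    id=f"{cls}_{i:04d}",
                    sequence=seq,
                    label=cls,
                    pssm=PSSMProfile(scores=scores, is_fallback=False),
                )
            )
    return LabeledDataset(records=records)


def simulate_null_labels(
    dataset: LabeledDataset, seed: int = 0
) -> LabeledDataset:
    """Uniformly permute the labels across records (class counts preserved)."""
    if not dataset.records:
        raise ValidationError("dataset is empty")
    rng = np.random.RandomState(seed)
    labels = [rec.label for rec in dataset.records]
    perm = rng.permutation(len(labels))
    shuffled = [
        ProteinRecord(
            id=rec.id, sequence=rec.sequence,
            label=labels[perm[i]], pssm=rec.pssm,
        )
        for i, rec in enumerate(dataset.records)
    ]
    return LabeledDataset(records=shuffled)


def write_dataset(
    dataset: LabeledDataset,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write FASTA + per-sequence PSSM files + label table (+ config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    with open(outdir / "sequences.fasta", "w") as fa, \
            open(outdir / "labels.tsv", "w") as lab:
        for rec in dataset.records:
            fa.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fa.write(rec.sequence[i:i + 60] + "\n")
            lab.write(f"{rec.id}\t{rec.label}\n")
            if rec.pssm is not None and not rec.pssm.is_fallback:
                write_pssm(rec.pssm, pssm_dir / f"{rec.id}.pssm", rec.sequence)
    if config is not None:
        payload = {
            "class_counts": dict(config.class_counts),
            "length_range": list(config.length_range),
            "composition_bias": config.composition_bias,
            "terminal_motif": config.terminal_motif,
            "pssm_signal": config.pssm_signal,
            "seed": config.seed,
        }
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
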