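"""Seeded synthetic two-class protein sequence generator.

Emulates the shape of a real enzyme/non-enzyme sequence collection — two
classes of variable-length sequences over the 20 standard residues — with a
controllable, known signal: in the positive class, chosen k-spaced residue
pairs are over-represented by overwriting the background draw at randomly
selected positions.  Overwriting (rather than inserting) keeps lengths fixed
and leaves the background residue marginal nearly intact, so the planted pair
signal is exactly what the selection stage must recover.

Defaults model the study conditions used throughout the test suite: 100
positive and 100 negative sequences, lengths uniform on [100, 400], uniform
residue background, and the pairs A···A and L···L at gap k = 3 enriched in
positives with overwrite rate 0.15 per eligible position.  All randomness
flows from a single integer seed through one shared generator stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .encoding import ALPHABET, FeatureDescriptor
from .sequence_io import LabeledDataset, ProteinSequence, write_fasta

__all__ = [
    "EnrichedPair",
    "GeneratorConfig",
    "generate_sequence",
    "generate_dataset",
    "write_dataset",
]

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class EnrichedPair:
    """A k-spaced pair (i, j) planted at *rate* per eligible start position."""

    i: str
    j: str
    k: int
    rate: float

    def __post_init__(self) -> None:
        if self.i not in _AA_INDEX or self.j not in _AA_INDEX:
            raise ValueError(f"unknown residue in pair ({self.i!r}, {self.j!r})")
        if self.k < 0:
            raise ValueError("gap k must be >= 0")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"insertion rate must be in [0, 1], got {self.rate}")

    @property
    def descriptor(self) -> FeatureDescriptor:
        return FeatureDescriptor("CKSAAP", self.i, self.j, self.k)


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the two-class generator."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (100, 400)
    background: Optional[np.ndarray] = None  # uniform 0.05 each when None
    enriched_pairs: tuple[EnrichedPair, ...] = (
        EnrichedPair("A", "A", 3, 0.15),
        EnrichedPair("L", "L", 3, 0.15),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sequence")
        lo, hi = self.length_range
        max_k = max((p.k for p in self.enriched_pairs), default=0)
        if lo < max_k + 2:
            raise ValueError(
                f"minimum length {lo} < max gap + 2 = {max_k + 2}"
            )
        if lo > hi:
            raise ValueError("length_range must be (min, max) with min <= max")
        if self.background is None:
            self.background = np.full(20, 0.05)
        else:
            self.background = np.asarray(self.background, dtype=float)
        _check_background(self.background)

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "length_range": list(self.length_range),
            "background": self.background.tolist(),
            "enriched_pairs": [
                {"i": p.i, "j": p.j, "k": p.k, "rate": p.rate}
                for p in self.enriched_pairs
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_pos=d["n_pos"],
            n_neg=d["n_neg"],
            length_range=tuple(d["length_range"]),
            background=np.asarray(d["background"]),
            enriched_pairs=tuple(EnrichedPair(**p) for p in d["enriched_pairs"]),
            seed=d["seed"],
        )


def _check_background(background: np.ndarray) -> None:
    if background.shape != (20,):
        raise ValueError(f"background must have 20 components, got {background.shape}")
    if (background < 0).any() or not np.isclose(background.sum(), 1.0, atol=1e-8):
        raise ValueError("background probabilities must be nonnegative and sum to 1")


def generate_sequence(
    length: int,
    background: np.ndarray,
    enriched_pairs: Sequence[EnrichedPair],
    rng: np.random.Generator,
    seq_id: str = "seq",
) -> ProteinSequence:
    """Draw residues i.i.d. from *background*, then plant enriched pairs.

    For each enriched pair in order, every start position p with
    p + k + 1 < length is independently overwritten (positions p and p+k+1
    set to the pair residues) with probability equal to the pair's rate.
    """
    background = np.asarray(background, dtype=float)
    _check_background(background)
    max_k = max((p.k for p in enriched_pairs), default=0)
    if length < max_k + 2:
        raise ValueError(f"length {length} < max gap + 2 = {max_k + 2}")
    arr = rng.choice(20, size=length, p=background)
    for pair in enriched_pairs:
        span = length - pair.k - 1  # number of eligible start positions
        hits = np.flatnonzero(rng.random(span) < pair.rate)
        arr[hits] = _AA_INDEX[pair.i]
        arr[hits + pair.k + 1] = _AA_INDEX[pair.j]
    residues = "".join(ALPHABET[c] for c in arr)
    return ProteinSequence(id=seq_id, residues=residues)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[LabeledDataset, list[str]]:
    """Generate positives (with planted pairs) and background-only negatives.

    Returns the dataset and the ground-truth list of planted descriptor names
    (e.g. ``["A***A", "L***L"]``) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    seqs: list[ProteinSequence] = []
    labels: list[int] = []
    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(
            generate_sequence(
                length, config.background, config.enriched_pairs, rng,
                seq_id=f"pos_{i:04d}",
            )
        )
        labels.append(1)
    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(
            generate_sequence(
                length, config.background, (), rng, seq_id=f"neg_{i:04d}"
            )
        )
        labels.append(0)
    truth = [p.descriptor.name for p in config.enriched_pairs]
    return LabeledDataset(sequences=seqs, labels=np.array(labels)), truth


def write_dataset(
    out_dir: Union[str, Path],
    config: GeneratorConfig,
) -> dict[str, Path]:
    """Generate and write FASTA files, a TSV label table, and a manifest.

    Emits ``positives.fasta``/``negatives.fasta``, a combined ``labels.tsv``
    (id, label), and ``manifest.json`` recording the full config (seed
    included) and the ground-truth enriched descriptors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(config)
    pos = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 1]
    neg = [s for s, l in zip(dataset.sequences, dataset.labels) if l == 0]
    paths = {
        "positives": out_dir / "positives.fasta",
        "negatives": out_dir / "negatives.fasta",
        "labels": out_dir / "labels.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_fasta(pos, paths["positives"])
    write_fasta(neg, paths["negatives"])
    with open(paths["labels"], "w") as fh:
        for s, l in zip(dataset.sequences, dataset.labels):
            fh.write(f"{s.id}\t{int(l)}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"config": config.to_dict(), "ground_truth_pairs": truth}, fh, indent=1
        )
    return paths
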