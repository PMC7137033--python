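"""Seeded generators for labeled site-window datasets.

Signal is injected at the generative level — nucleotide probabilities, planted
trimers, positional overrides — never at the feature level, so the full
encoder and selection machinery are exercised and signal recovery is
nontrivial.  The central position is constitutively C and is never overwritten
by planting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from rna5hmc.sequence_io import (
    DEFAULT_WINDOW_LENGTH,
    LabeledDataset,
    SiteWindow,
    write_fasta,
)

ALPHABET = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model for one labeled dataset.

    Negatives are i.i.d. draws from ``background`` (center forced to C).
    Positives additionally receive, in order: an additive boost ``g_boost`` to
    P(G) (renormalized), a GGG trimer planted at a random non-center-touching
    position with per-sequence probability ``ggg_insert_rate``, and positional
    overrides ``(position, nucleotide, probability)`` that set the marginal
    probability of one nucleotide at a 1-based position.
    """

    n_pos: int = 600
    n_neg: int = 600
    L: int = DEFAULT_WINDOW_LENGTH
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    g_boost: float = 0.0
    ggg_insert_rate: float = 0.0
    positional_enrichments: tuple[tuple[int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 5 or self.L % 2 == 0:
            raise ValueError("L must be odd and >= 5")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        bg = np.asarray(self.background, dtype=float)
        if len(bg) != 4 or np.any(bg < 0) or bg.sum() <= 0:
            raise ValueError("background must be 4 non-negative probabilities")
        if self.g_boost < 0:
            raise ValueError("g_boost must be >= 0")
        if not 0.0 <= self.ggg_insert_rate <= 1.0:
            raise ValueError("ggg_insert_rate must be in [0, 1]")
        center = (self.L + 1) // 2
        for pos, nt, prob in self.positional_enrichments:
            if not 1 <= pos <= self.L:
                raise ValueError(f"enrichment position {pos} outside 1..{self.L}")
            if nt not in "ACGU":
                raise ValueError(f"enrichment nucleotide {nt!r} not in ACGU")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("enrichment probability must be in [0, 1]")
            if pos == center and nt != "C":
                raise ValueError("cannot enrich a non-C nucleotide at the center")

    @property
    def center(self) -> int:
        return (self.L + 1) // 2

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["background"] = tuple(raw["background"])
        raw["positional_enrichments"] = tuple(
            (int(p), str(n), float(q)) for p, n, q in raw["positional_enrichments"]
        )
        return cls(**raw)


def _normalized(p: np.ndarray) -> np.ndarray:
    return p / p.sum()


def _draw_windows(rng: np.random.Generator, n: int, L: int, probs: np.ndarray) -> np.ndarray:
    # (n, L) character array; center set to C afterwards by the caller
    idx = rng.choice(4, size=(n, L), p=probs)
    return ALPHABET[idx]


def generate(config: SimConfig) -> LabeledDataset:
    """Generate a labeled dataset, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    bg = _normalized(np.asarray(config.background, dtype=float))
    center0 = config.center - 1  # 0-based

    pos_probs = bg.copy()
    pos_probs[ALPHABET.tolist().index("G")] += config.g_boost
    pos_probs = _normalized(pos_probs)

    pos = _draw_windows(rng, config.n_pos, config.L, pos_probs)

    # plant one GGG per selected positive at a start whose 3-window avoids the center
    valid_starts = np.array(
        [s for s in range(config.L - 2) if not (s <= center0 <= s + 2)]
    )
    planted = rng.random(config.n_pos) < config.ggg_insert_rate
    starts = rng.choice(valid_starts, size=config.n_pos)
    for i in np.flatnonzero(planted):
        pos[i, starts[i] : starts[i] + 3] = "G"

    # positional overrides: marginal P(nt at pos) = prob, remaining mass split
    # over the other nucleotides proportionally to the background
    for position, nt, prob in config.positional_enrichments:
        j = position - 1
        nt_i = ALPHABET.tolist().index(nt)
        others = np.delete(np.arange(4), nt_i)
        other_p = _normalized(bg[others]) * (1 - prob)
        full = np.empty(4)
        full[nt_i] = prob
        full[others] = other_p
        pos[:, j] = ALPHABET[rng.choice(4, size=config.n_pos, p=full)]

    neg = _draw_windows(rng, config.n_neg, config.L, bg)
    pos[:, center0] = "C"
    neg[:, center0] = "C"

    windows = [
        SiteWindow(id=f"pos_{i+1:05d}", seq="".join(row)) for i, row in enumerate(pos)
    ] + [
        SiteWindow(id=f"neg_{i+1:05d}", seq="".join(row)) for i, row in enumerate(neg)
    ]
    labels = [1] * config.n_pos + [0] * config.n_neg
    return LabeledDataset(windows=windows, labels=labels, provenance=f"synthetic seed={config.seed}")


# Canned scenarios with fixed, documented seeds.
PRESETS: dict[str, SimConfig] = {
    "null_small": SimConfig(n_pos=50, n_neg=50, seed=101),
    "strong_kmer": SimConfig(n_pos=600, n_neg=600, g_boost=0.5, ggg_insert_rate=0.3, seed=202),
    "positional_only": SimConfig(
        n_pos=600, n_neg=600, positional_enrichments=((38, "A", 0.75),), seed=303
    ),
    "mixed": SimConfig(
        n_pos=600, n_neg=600, g_boost=0.15, ggg_insert_rate=0.2,
        positional_enrichments=((38, "A", 0.6),), seed=404,
    ),
}

# Non-uniform composition preset; illustrative only, not calibrated to any
# real transcriptome.
SKEWED_BACKGROUND = (0.28, 0.22, 0.22, 0.28)


def fixture_suite() -> dict[str, LabeledDataset]:
    """Generate every preset scenario with its documented seed."""
    return {name: generate(cfg) for name, cfg in PRESETS.items()}


def write_dataset(
    dataset: LabeledDataset, config: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit positives/negatives FASTA plus a JSON sidecar with the SimConfig."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "positives": outdir / "positives.fasta",
        "negatives": outdir / "negatives.fasta",
        "config": outdir / "simconfig.json",
    }
    write_fasta(dataset.positives(), paths["positives"])
    write_fasta(dataset.negatives(), paths["negatives"])
    config.to_json(paths["config"])
    return paths
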