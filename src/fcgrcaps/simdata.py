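"""Synthetic DNA benchmarks with the statistical shape of enhancer data.

The only class contrast the enhancer benchmark documents quantitatively is
nucleotide composition: enhancers run GC-richer than nonenhancers, and strong
enhancers GC-richer than weak ones.  The generator therefore draws each
position i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2 at a fixed
length (200 bp by default), and can additionally plant exact k-mer motifs so
that k-mer-resolution claims are testable independently of GC content.

Default class GC fractions: nonenhancer 0.40, enhancer 0.60, strong 0.65,
weak 0.55 — ordered strong > weak > nonenhancer.  Every dataset carries a
manifest from which it can be regenerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fcgr import SequenceRecord

__all__ = [
    "ClassProfile",
    "SyntheticDataset",
    "TwoStageBenchmark",
    "DEFAULT_PROFILES",
    "generate_class",
    "plant_motif",
    "generate_two_stage_benchmark_like",
    "regenerate",
]

GENERATOR_VERSION = 1


@dataclass(frozen=True)
class ClassProfile:
    """Generative profile of one sequence class."""

    label: str
    gc_fraction: float
    length: int = 200
    motifs: tuple[tuple[str, float], ...] = ()  # (k-mer, per-sequence probability)

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0, 1], got {self.gc_fraction}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        for motif, prob in self.motifs:
            if len(motif) > self.length:
                raise ValueError(f"motif {motif!r} longer than sequence length {self.length}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"motif probability must be in [0, 1], got {prob}")

    def to_manifest(self) -> dict:
        return {"label": self.label, "gc_fraction": self.gc_fraction,
                "length": self.length, "motifs": [list(m) for m in self.motifs]}

    @staticmethod
    def from_manifest(d: dict) -> "ClassProfile":
        return ClassProfile(d["label"], d["gc_fraction"], d["length"],
                            tuple((m, p) for m, p in d.get("motifs", [])))


DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "nonenhancer": ClassProfile("nonenhancer", 0.40),
    "enhancer": ClassProfile("enhancer", 0.60),
    "strong": ClassProfile("strong", 0.65),
    "weak": ClassProfile("weak", 0.55),
}


@dataclass
class SyntheticDataset:
    """Labeled records plus the manifest that regenerates them."""

    records: list[SequenceRecord]
    manifest: dict = field(default_factory=dict)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]


def plant_motif(residues: str, motif: str, rng: np.random.Generator) -> str:
    """Substitute ``motif`` in place at a uniform-random offset; length is
    preserved."""
    if len(motif) > len(residues):
        raise ValueError(f"motif {motif!r} longer than sequence ({len(residues)} nt)")
    pos = int(rng.integers(0, len(residues) - len(motif) + 1))
    return residues[:pos] + motif + residues[pos + len(motif):]


def generate_class(n: int, profile: ClassProfile, seed: int | np.random.Generator,
                   id_prefix: str | None = None) -> list[SequenceRecord]:
    """Draw ``n`` i.i.d. sequences from a class profile, deterministically
    under ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gc = profile.gc_fraction
    probs = [(1.0 - gc) / 2.0, gc / 2.0, gc / 2.0, (1.0 - gc) / 2.0]  # A C G T
    alphabet = np.array(list("ACGT"))
    prefix = id_prefix if id_prefix is not None else profile.label
    records = []
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=profile.length, p=probs))
        for motif, prob in profile.motifs:
            if rng.random() < prob:
                seq = plant_motif(seq, motif, rng)
        records.append(SequenceRecord(f"{prefix}_{i:05d}", seq, profile.label))
    return records


@dataclass
class TwoStageBenchmark:
    """Stage-1 (enhancer vs nonenhancer) and stage-2 (strong vs weak)
    training sets plus a disjoint independent test set."""

    stage1: SyntheticDataset
    stage2: SyntheticDataset
    test: SyntheticDataset
    manifest: dict = field(default_factory=dict)

    def test_stage1_labels(self) -> np.ndarray:
        """Stage-1 view of the test set: strong/weak collapse to enhancer."""
        return np.array(["enhancer" if r.label in ("strong", "weak") else "nonenhancer"
                         for r in self.test.records])


def generate_two_stage_benchmark_like(
        sizes: tuple[int, int, int, int] = (1484, 1484, 742, 742),
        test_sizes: tuple[int, int, int] = (100, 100, 200),
        profiles: dict[str, ClassProfile] | None = None,
        seed: int = 0) -> TwoStageBenchmark:
    """Generate a two-stage benchmark-shaped dataset at any scale.

    ``sizes`` = (n_enhancer, n_nonenhancer, n_strong, n_weak) training
    counts; ``test_sizes`` = (strong, weak, nonenhancer) independent test
    counts.  Stage-1 enhancers are drawn half from the strong and half from
    the weak profile (enhancers are the pooled strength classes); the test
    set serves stage 1 (strong+weak = positive) and stage 2 (strong vs weak)
    simultaneously.  All ids are disjoint across the three sets.
    """
    profiles = dict(DEFAULT_PROFILES, **(profiles or {}))
    n_enh, n_non, n_str, n_wk = sizes
    if min(sizes) < 2 or min(test_sizes) < 1:
        raise ValueError(f"all training sizes must be >= 2, got {sizes}")
    if profiles["strong"].gc_fraction <= profiles["weak"].gc_fraction:
        warnings.warn("profile GC ordering violates strong > weak", stacklevel=2)
    rng = np.random.default_rng(seed)

    half = n_enh // 2
    enh = (generate_class(half, _relabel(profiles["strong"], "enhancer"), rng, "tr_enh_s")
           + generate_class(n_enh - half, _relabel(profiles["weak"], "enhancer"), rng, "tr_enh_w"))
    non = generate_class(n_non, profiles["nonenhancer"], rng, "tr_non")
    strong = generate_class(n_str, profiles["strong"], rng, "tr_strong")
    weak = generate_class(n_wk, profiles["weak"], rng, "tr_weak")
    t_strong = generate_class(test_sizes[0], profiles["strong"], rng, "te_strong")
    t_weak = generate_class(test_sizes[1], profiles["weak"], rng, "te_weak")
    t_non = generate_class(test_sizes[2], profiles["nonenhancer"], rng, "te_non")

    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": int(seed),
        "sizes": list(sizes),
        "test_sizes": list(test_sizes),
        "profiles": {k: v.to_manifest() for k, v in profiles.items()},
    }
    return TwoStageBenchmark(
        stage1=SyntheticDataset(enh + non, manifest),
        stage2=SyntheticDataset(strong + weak, manifest),
        test=SyntheticDataset(t_strong + t_weak + t_non, manifest),
        manifest=manifest,
    )


def _relabel(profile: ClassProfile, label: str) -> ClassProfile:
    return ClassProfile(label, profile.gc_fraction, profile.length, profile.motifs)


def regenerate(manifest: dict) -> TwoStageBenchmark:
    """Rebuild the exact dataset a manifest describes."""
    if manifest.get("generator_version") != GENERATOR_VERSION:
        raise ValueError(f"unsupported generator version {manifest.get('generator_version')}")
    profiles = {k: ClassProfile.from_manifest(v) for k, v in manifest["profiles"].items()}
    return generate_two_stage_benchmark_like(
        tuple(manifest["sizes"]), tuple(manifest["test_sizes"]), profiles, manifest["seed"])
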