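"""Synthetic guide datasets and screen counts with planted ground truth.

Real guide-efficiency corpora (genome-scale E. coli screens, human viability
screens) cannot ship with the package, so every pipeline stage is exercised
on synthetic data whose generating process is fully known:

* :func:`generate` draws random 20-nt guides and builds their efficiency as a
  linear combination of *encoder-producible* features (plus optional pairwise
  interaction terms), Gaussian noise, and a monotone skew transform — so the
  response distribution can be asymmetric, as empirical cutting-efficiency
  scores are, while min-max normalization must preserve that shape.
* :func:`generate_regression` is the numeric planted-signal benchmark
  (informative columns among pure-noise columns) used to test importance
  recovery and the iteration-to-iteration amplification of the weighted
  forest.
* :func:`generate_counts` emulates a pooled depletion screen: binomial read
  counts per run around per-design true abundance ratios, including a spiked
  wash-control design.

Every generator is deterministic per seed and returns a ground-truth ledger
recording the planted coefficients, so tests never re-derive truth from the
data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import encode
from .encode import Guide

DEFAULT_NOISE_SD = 0.5


class SynthSpecError(ValueError):
    """Planted effect refers to a feature the encoder cannot produce."""


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a planted-structure guide dataset.

    ``planted_effects`` name encoder feature columns (raw names like ``gc``
    or ``tm``, one-hot names like ``G@20``, count names like ``count_GG``)
    with their linear coefficients; ``interaction_effects`` add products of
    feature pairs.  ``skew`` applies a monotone power transform to the
    response (1 = none), emulating the asymmetric score distributions of real
    screens.
    """

    n_guides: int
    seed: int
    planted_effects: tuple[tuple[str, float], ...] = ()
    interaction_effects: tuple[tuple[tuple[str, ...], float], ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    skew: float = 1.0
    gc_bias: float | None = None  # per-position P(G or C); None = uniform
    species_mix: tuple[tuple[str, float], ...] = (("ecoli", 1.0),)

    def __post_init__(self):
        if self.n_guides < 1:
            raise SynthSpecError("n_guides must be >= 1")
        if self.noise_sd < 0:
            raise SynthSpecError("noise_sd must be >= 0")
        if self.skew <= 0:
            raise SynthSpecError("skew must be > 0")


def _random_sequences(n: int, rng: np.random.Generator, gc_bias: float | None) -> list[str]:
    if gc_bias is None:
        probs = np.full(4, 0.25)
    else:
        probs = np.array(
            [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
        )
    bases = np.array(list("ACGT"))
    draws = rng.choice(4, size=(n, encode.GUIDE_LENGTH), p=probs)
    return ["".join(bases[row]) for row in draws]


def _planted_feature_columns(
    guides: Sequence[Guide], names: Sequence[str]
) -> pd.DataFrame:
    """Resolve planted feature names against the encoder's producible columns."""
    pool = pd.concat(
        [
            encode.raw_features(guides, features=("gc", "tm")),
            encode.onehot_positional(guides),
            encode.position_independent_counts(guides),
        ],
        axis=1,
    )
    missing = [n for n in names if n not in pool.columns]
    if missing:
        raise SynthSpecError(
            f"planted feature(s) not producible by the encoder: {missing}"
        )
    return pool[list(names)]


def generate(spec: SynthSpec) -> tuple[list[Guide], dict]:
    """Guides with planted feature-efficiency structure plus a truth ledger."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6D]))
    seqs = _random_sequences(spec.n_guides, rng, spec.gc_bias)

    species_names = [s for s, _ in spec.species_mix]
    species_probs = np.array([w for _, w in spec.species_mix], dtype=float)
    species_probs = species_probs / species_probs.sum()
    species = rng.choice(species_names, size=spec.n_guides, p=species_probs)

    pam_n = rng.choice(list("ACGT"), size=spec.n_guides)
    distances = rng.integers(0, 200, size=spec.n_guides)
    locations = rng.choice(encode.GENE_LOCATIONS, size=spec.n_guides)

    bare = [Guide(seq=s) for s in seqs]
    names = [n for n, _ in spec.planted_effects]
    for fs, _ in spec.interaction_effects:
        names.extend(fs)
    names = list(dict.fromkeys(names))  # stable dedupe
    cols = _planted_feature_columns(bare, names) if names else pd.DataFrame(index=range(spec.n_guides))

    y = np.zeros(spec.n_guides)
    for name, coef in spec.planted_effects:
        y = y + coef * cols[name].to_numpy(dtype=float)
    for fs, coef in spec.interaction_effects:
        term = np.ones(spec.n_guides)
        for name in fs:
            term = term * cols[name].to_numpy(dtype=float)
        y = y + coef * term
    y = y + rng.normal(0.0, spec.noise_sd, spec.n_guides)
    if spec.skew != 1.0 and np.ptp(y) > 0:
        # monotone power transform on the unit-scaled response
        z = (y - y.min()) / np.ptp(y)
        y = y.min() + np.ptp(y) * z**spec.skew

    guides = [
        Guide(
            seq=seqs[i],
            pam=f"{pam_n[i]}GG",
            efficiency=float(y[i]),
            distance_to_pam=int(distances[i]),
            gene_location=str(locations[i]),
            species=str(species[i]),
        )
        for i in range(spec.n_guides)
    ]
    truth = {
        "planted_effects": {n: c for n, c in spec.planted_effects},
        "interaction_effects": {
            "+".join(fs): c for fs, c in spec.interaction_effects
        },
        "noise_sd": spec.noise_sd,
        "skew": spec.skew,
        "seed": spec.seed,
    }
    return guides, truth


def generate_regression(
    n: int,
    n_noise: int,
    coefs: Sequence[float] = (3.0, 2.0),
    interaction_coefs: Mapping[tuple[int, int], float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Numeric planted-signal benchmark for importance recovery.

    ``X`` is ``n x (len(coefs) + n_noise)`` standard normal; the first
    ``len(coefs)`` columns are informative (``y = X @ coefs + interactions +
    N(0, noise_sd)``), the rest pure noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E5]))
    p = len(coefs) + n_noise
    X = rng.normal(size=(n, p))
    y = X[:, : len(coefs)] @ np.asarray(coefs, dtype=float)
    interaction_coefs = interaction_coefs or {}
    for (i, j), c in interaction_coefs.items():
        y = y + c * X[:, i] * X[:, j]
    y = y + rng.normal(0.0, noise_sd, n)
    truth = {
        "informative": list(range(len(coefs))),
        "coefs": list(coefs),
        "interactions": {f"{i}+{j}": c for (i, j), c in interaction_coefs.items()},
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return X, y, truth


def generate_counts(
    n_designs: int,
    true_delta: float | Sequence[float] = 1.0,
    seed: int = 0,
    donor_runs: int = 3,
    host_runs: int = 2,
    reads_per_design: int = 10_000,
    dispersion: float = 0.05,
    wash_id: str = "WASH",
    wash_abundance: float = 1e-7,
) -> tuple[pd.DataFrame, dict]:
    """Long-format pooled-screen count table with known depletion.

    Each design's donor abundance is ~1/n_designs; its expected host
    abundance is that times its true delta, with per-run lognormal dispersion
    and binomial read sampling at an expected depth of ``reads_per_design``
    perfect reads per run.  A spiked wash-control design (tiny constant
    abundance) is included for the correction step.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    deltas = np.broadcast_to(np.asarray(true_delta, dtype=float), (n_designs,))
    base_ab = 1.0 / n_designs
    merged = int(reads_per_design / base_ab)

    rows = []
    for lib, n_runs in (("donor", donor_runs), ("host", host_runs)):
        for run in range(1, n_runs + 1):
            run_id = f"{lib}{run}"
            for d in range(n_designs):
                mean_ab = base_ab * (deltas[d] if lib == "host" else 1.0)
                ab = mean_ab * rng.lognormal(0.0, dispersion)
                reads = rng.binomial(merged, min(ab, 1.0))
                rows.append(
                    {
                        "design_id": f"D{d + 1:04d}",
                        "run_id": run_id,
                        "library": lib,
                        "perfect_reads": int(reads),
                        "merged_pairs": merged,
                    }
                )
            rows.append(
                {
                    "design_id": wash_id,
                    "run_id": run_id,
                    "library": lib,
                    "perfect_reads": int(rng.binomial(merged, wash_abundance)),
                    "merged_pairs": merged,
                }
            )
    truth = {
        "true_delta": list(map(float, deltas)),
        "wash_id": wash_id,
        "wash_abundance": wash_abundance,
        "reads_per_design": reads_per_design,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth
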