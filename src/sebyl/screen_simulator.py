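"""Forward simulator of the pooled mother-enrichment lifespan screen.

Generates the data the estimator consumes — UPTAG/DNTAG count tables for the
unsorted culture and the young/old fractions of each sorting round, together
with sort metadata and a ground-truth table — from known per-strain Gompertz
mortality. The generative model mirrors the experiment:

* a biotin-labeled mother cohort per strain ages by ``growth_gens``
  generations per culture period; each mother survives a period with the
  conditional Gompertz probability ``S_i(G_end) / S_i(G_start)``
  (binomial draw);
* daughters accumulate as ``2**growth_gens - 1`` per surviving mother per
  period (expected-value bookkeeping — daughters only matter through the
  young-pool fractions);
* magnetic-bead sorting recovers each surviving mother with probability
  ``r_true`` (binomial); recovered mothers seed the next round;
* sequencing draws Multinomial(depth, pool fractions) counts per sample,
  independently for the two tag classes.

An expectation mode replaces every random draw with its expectation, giving
exact deterministic fixtures; ``simulate_reads`` additionally renders counts
into synthetic FASTQ with a configurable per-base substitution error.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .barcode_decode import BarcodeLibrary, CountTable, DecodeConfig, TagClass
from .lifespan_model import SortMetadata

__all__ = [
    "SimConfig",
    "SimTruth",
    "median_to_b",
    "random_barcode_library",
    "simulate_pool",
    "simulate_reads",
]

LN2 = math.log(2.0)


def median_to_b(median_g, c) -> np.ndarray:
    """Back-solve the Gompertz rate b from a target median lifespan at
    fixed shape c: median = ln(ln2/b)/ln(c)  =>  b = ln2 * c**(-median)."""
    median_g = np.asarray(median_g, dtype=float)
    return LN2 * np.asarray(c, dtype=float) ** (-median_g)


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated screen.

    Defaults describe a desk-scale version of the pooled experiment: four
    sorting rounds, ~4 generations of growth per period, 1e7 labeled starting
    mothers, bead recovery 0.6 per round and 5e6 reads per sample. True
    mortality is Gompertz per strain; supply (b, c) arrays directly or let
    ``median_range`` sample true medians uniformly and back-solve b at fixed
    shape ``c_fixed``.
    """

    n_strains: int = 100
    b: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    median_range: Tuple[float, float] = (15.0, 40.0)
    c_fixed: float = 1.15
    growth_gens: float | np.ndarray = 4.0
    rounds: int = 4
    N0: float = 1e7
    r_true: float = 0.6
    depth: int = 5_000_000
    noise: float = 0.01           # per-base substitution rate for FASTQ emission
    expectation_mode: bool = False
    initial_fractions: Optional[np.ndarray] = None
    strain_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.rounds < 1:
            raise ValueError("need >= 1 strain and >= 1 round")
        if not (0 < self.r_true <= 1):
            raise ValueError("r_true must lie in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.noise < 1):
            raise ValueError("noise must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth for recovery testing."""

    strain_ids: list[str]
    b: np.ndarray
    c: np.ndarray
    median_g: np.ndarray
    survivors: np.ndarray       # strains x rounds, mothers alive at end of period
    recovered: np.ndarray       # strains x rounds, mothers captured by sorting
    daughters: np.ndarray       # strains x rounds, daughter-pool abundance

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"b": self.b, "c": self.c, "median_g": self.median_g},
                          index=pd.Index(self.strain_ids, name="strain_id"))
        for k in range(self.survivors.shape[1]):
            df[f"survivors_{k + 1}"] = self.survivors[:, k]
            df[f"recovered_{k + 1}"] = self.recovered[:, k]
            df[f"daughters_{k + 1}"] = self.daughters[:, k]
        return df


def _resolve_params(config: SimConfig, rng: np.random.Generator):
    n = config.n_strains
    if config.b is not None:
        b = np.asarray(config.b, dtype=float)
        c = np.asarray(config.c if config.c is not None else
                       np.full(n, config.c_fixed), dtype=float)
    else:
        lo, hi = config.median_range
        med = rng.uniform(lo, hi, size=n)
        c = np.full(n, config.c_fixed)
        b = median_to_b(med, c)
    if b.shape != (n,) or c.shape != (n,):
        raise ValueError("b and c must have length n_strains")
    if np.any(b <= 0) or np.any(c <= 1):
        raise ValueError("require b > 0 and c > 1 for every strain")
    median = np.where(b < LN2, np.log(LN2 / b) / np.log(c), 0.0)
    return b, c, median


def simulate_pool(
    config: SimConfig, seed: Optional[int] = None
) -> Tuple[CountTable, CountTable, SortMetadata, SimTruth]:
    """Simulate the full pooled aging experiment.

    Returns UPTAG and DNTAG count tables over the canonical sample layout
    (USC, S1Y..SNY, S1O..SNO), the matching :class:`SortMetadata` (To/Ty set
    to simulated totals, r set to ``r_true``), and the :class:`SimTruth`
    oracle. Fully reproducible for a given seed; in expectation mode all
    draws are replaced by expectations and counts are real-valued.
    """
    rng = np.random.default_rng(seed)
    n, rounds = config.n_strains, config.rounds
    b, c, median = _resolve_params(config, rng)
    strain_ids = (list(config.strain_ids) if config.strain_ids is not None
                  else [f"strain{i:04d}" for i in range(n)])
    if len(strain_ids) != n:
        raise ValueError("strain_ids length must equal n_strains")
    growth = np.broadcast_to(np.asarray(config.growth_gens, dtype=float), (n,))

    if config.initial_fractions is not None:
        f0 = np.asarray(config.initial_fractions, dtype=float)
        f0 = f0 / f0.sum()
    else:
        f0 = np.full(n, 1.0 / n)

    exp_mode = config.expectation_mode
    if exp_mode:
        mothers = config.N0 * f0
    else:
        mothers = rng.multinomial(int(config.N0), f0).astype(float)

    survivors = np.zeros((n, rounds))
    recovered = np.zeros((n, rounds))
    daughters = np.zeros((n, rounds))
    To = np.zeros(rounds + 1)
    Ty = np.zeros(rounds + 1)
    To[0] = Ty[0] = mothers.sum()

    frac_pools: dict[str, np.ndarray] = {"USC": mothers / mothers.sum()}
    g_age = np.zeros(n)
    for k in range(1, rounds + 1):
        g_next = g_age + growth
        # conditional Gompertz survival over the period:
        # exp(-b*(c**g_next - c**g_age)), numerically safe elementwise
        p_surv = np.exp(-np.clip(b * (c ** g_next - c ** g_age), 0.0, 700.0))
        if exp_mode:
            surv = mothers * p_surv
            rec = surv * config.r_true
        else:
            surv = rng.binomial(mothers.astype(np.int64), p_surv).astype(float)
            rec = rng.binomial(surv.astype(np.int64), config.r_true).astype(float)
        dght = surv * (2.0 ** growth - 1.0)
        survivors[:, k - 1] = surv
        recovered[:, k - 1] = rec
        daughters[:, k - 1] = dght
        ty = dght.sum()
        to = rec.sum()
        if to <= 0 or ty <= 0:
            raise RuntimeError(f"pool extinct at round {k}")
        Ty[k] = ty
        To[k] = to
        frac_pools[f"S{k}Y"] = dght / ty
        frac_pools[f"S{k}O"] = rec / to
        mothers = rec
        g_age = g_next

    samples = (["USC"] + [f"S{k}Y" for k in range(1, rounds + 1)]
               + [f"S{k}O" for k in range(1, rounds + 1)])
    roles = {"USC": ("unsorted", 0)}
    for k in range(1, rounds + 1):
        roles[f"S{k}Y"] = ("young", k)
        roles[f"S{k}O"] = ("old", k)

    def draw_counts() -> np.ndarray:
        cols = []
        for s in samples:
            f = frac_pools[s]
            if exp_mode:
                cols.append(config.depth * f)
            else:
                cols.append(rng.multinomial(config.depth, f).astype(float))
        return np.column_stack(cols)

    up = CountTable(strain_ids, samples, draw_counts(), TagClass.UPTAG)
    dn = CountTable(strain_ids, samples, draw_counts(), TagClass.DNTAG)
    meta = SortMetadata(To, Ty, np.full(rounds, config.r_true), roles)
    truth = SimTruth(strain_ids, b, c, median, survivors, recovered, daughters)
    return up, dn, meta, truth


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, noise: float, rng: np.random.Generator) -> str:
    if noise <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < noise)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def random_barcode_library(
    n_strains: int,
    tag_length: int = 20,
    min_distance: int = 8,
    seed: Optional[int] = None,
    strain_ids: Optional[Sequence[str]] = None,
) -> BarcodeLibrary:
    """Random library whose barcodes keep a minimum pairwise edit distance.

    Candidate tags are drawn uniformly and kept greedily while they stay at
    least ``min_distance`` edits from every accepted tag of the same class —
    mirroring the well-separated 20-mers of the real deletion collection.
    """
    import edlib

    rng = np.random.default_rng(seed)
    kept: dict[TagClass, list[str]] = {TagClass.UPTAG: [], TagClass.DNTAG: []}
    for cls in (TagClass.UPTAG, TagClass.DNTAG):
        attempts = 0
        while len(kept[cls]) < n_strains:
            attempts += 1
            if attempts > 1000 * n_strains:
                raise RuntimeError("cannot satisfy the distance constraint")
            tag = "".join("ACGT"[i] for i in rng.integers(0, 4, tag_length))
            if all(edlib.align(tag, t, task="distance",
                               k=min_distance - 1)["editDistance"] == -1
                   for t in kept[cls]):
                kept[cls].append(tag)
    ids = (list(strain_ids) if strain_ids is not None
           else [f"strain{i:04d}" for i in range(n_strains)])
    entries = {s: (kept[TagClass.UPTAG][i], kept[TagClass.DNTAG][i])
               for i, s in enumerate(ids)}
    return BarcodeLibrary(entries, tag_length=tag_length)


def simulate_reads(
    counts: CountTable,
    library: BarcodeLibrary,
    decode_config: DecodeConfig,
    out_dir: str | Path,
    noise: float = 0.0,
    seed: Optional[int] = None,
    gz: bool = False,
) -> dict[str, Path]:
    """Render a count table into per-sample synthetic FASTQ files.

    Each count becomes one read ``adapter5 + tag + adapter3`` for the table's
    tag class, with every base substituted independently with probability
    ``noise``. Deterministic under ``seed``. Returns sample_id -> file path.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a5, a3 = decode_config.adapters(counts.tag_class)
    tags = library.tags(counts.tag_class)
    paths: dict[str, Path] = {}
    suffix = ".fastq.gz" if gz else ".fastq"
    for j, sample in enumerate(counts.samples):
        path = out_dir / f"{sample}_{counts.tag_class.value}{suffix}"
        opener = gzip.open if gz else open
        with opener(path, "wt") as fh:
            rid = 0
            for i, strain in enumerate(counts.strains):
                n_reads = int(round(float(counts.counts[i, j])))
                if n_reads <= 0:
                    continue
                if strain not in tags:
                    raise ValueError(f"strain {strain!r} lacks a "
                                     f"{counts.tag_class.value} barcode")
                template = a5 + tags[strain] + a3
                for _ in range(n_reads):
                    read = _mutate(template, noise, rng)
                    fh.write(f"@{sample}:{rid}\n{read}\n+\n{'I' * len(read)}\n")
                    rid += 1
        paths[sample] = path
    return paths
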