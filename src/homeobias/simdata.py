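"""Synthetic hybrid-transcriptome experiments with planted ground truth.

The generator emulates the design of a two-parent/F1 chilling study:
two parental transcript sets joined 1:1 into homeolog pairs, three
taxa (P1, P2, F1), three ordered conditions, and three biological
replicates per taxon per condition.  Read counts are drawn from a
negative-binomial distribution (variance = mu + phi*mu^2; phi = 0
degenerates to Poisson).

Each pair carries, per condition, a planted expression pattern bin
(no change, additivity, expression-level dominance toward either
parent, transgressive up/down) that fixes the parental means and the
hybrid's total expression, and a planted homeolog bias B that splits
the hybrid total between the two homeologs with P1-share
``2**B / (1 + 2**B)`` in expression space.  Expected counts respect
transcript lengths (count mean = expression * length/1000 at the
nominal depth of one million mapped reads), so the length-adjusted
null of the bias test is exercised non-trivially.

All randomness flows from a single :class:`numpy.random.Generator`
seeded from ``SimConfig.seed``; identical configurations produce
byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from homeobias.eld import BINS

__all__ = ["SimConfig", "SimResult", "simulate_experiment", "write_fixture"]

#: Nominal mapped-read total per simulated library.
NOMINAL_LIBRARY_SIZE = 1_000_000


def _default_pattern_frequencies() -> dict[str, float]:
    # a no-change-dominated mixture resembling hybrid transcriptomes
    return {
        "no_change": 0.60,
        "additivity": 0.05,
        "ELD_P1": 0.10,
        "ELD_P2": 0.20,
        "transgressive_up": 0.025,
        "transgressive_down": 0.025,
    }


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Attributes
    ----------
    n_pairs
        Number of homeolog pairs.
    n_replicates
        Biological replicates per taxon per condition.
    conditions
        Ordered condition labels (consecutive contrasts follow this order).
    baseline_mean
        Expected read count per transcript at the nominal depth.
    baseline_log_sd
        Natural-log SD of the mean-preserving lognormal spread of per-pair
        baseline expression (0 = all pairs at the same level).
    dispersion
        Negative-binomial dispersion phi (variance = mu + phi*mu^2).
    pattern_frequencies
        Sampling distribution over the six pattern bins, per pair per
        condition.
    parental_fold
        Fold separation between parental means when a pattern requires
        the parents to differ.
    transgressive_fold
        Factor by which transgressive hybrids exceed the parental range.
    bias_fraction, bias_sd
        A pair is biased with probability ``bias_fraction``; its base
        bias is drawn Normal(0, ``bias_sd``) (in log2 units), else 0.
    delta_fraction, delta_shift
        Fraction of pairs whose bias shifts by ±``delta_shift`` at one
        randomly chosen consecutive-condition boundary (planted ΔHEB).
    length_range
        Inclusive transcript-length bounds in bp.
    seed
        Seed for the single random generator driving everything.
    """

    n_pairs: int = 200
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("30C", "16C", "4C")
    baseline_mean: float = 200.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    pattern_frequencies: dict[str, float] = field(
        default_factory=_default_pattern_frequencies
    )
    parental_fold: float = 4.0
    transgressive_fold: float = 4.0
    bias_fraction: float = 0.3
    bias_sd: float = 2.0
    delta_fraction: float = 0.0
    delta_shift: float = 2.0
    length_range: tuple[int, int] = (500, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for downstream t-tests")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        unknown = set(self.pattern_frequencies) - set(BINS)
        if unknown:
            raise ValueError(f"unknown pattern bins: {sorted(unknown)}")
        freqs = np.array([self.pattern_frequencies.get(b, 0.0) for b in BINS])
        if (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("pattern_frequencies must be non-negative and sum to 1")
        if not 0 <= self.bias_fraction <= 1 or not 0 <= self.delta_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)


@dataclass
class SimResult:
    """Matrices, metadata and ground truth of one simulated experiment."""

    counts_p1: pd.DataFrame
    counts_p2: pd.DataFrame
    counts_f1: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame
    library_sizes: pd.Series
    truth: pd.DataFrame
    config: SimConfig


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial counts with mean/dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)  # = 1 / (1 + phi * mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Generate count matrices, metadata and the planted-truth table."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    n_cond = len(cfg.conditions)
    reps = cfg.n_replicates

    pair_ids = np.array([f"pair{i:05d}" for i in range(n)])
    spt_ids = np.array([f"P1t{i:05d}" for i in range(n)])
    spc_ids = np.array([f"P2t{i:05d}" for i in range(n)])
    len_spt = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=n)
    len_spc = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=n)

    # per-pair baseline expression, mean-preserving lognormal around the
    # level that yields `baseline_mean` expected counts at the mean length
    mean_len = 0.5 * (cfg.length_range[0] + cfg.length_range[1])
    e_base = cfg.baseline_mean * 1000.0 / mean_len
    sigma = cfg.baseline_log_sd
    base_expr = e_base * np.exp(rng.normal(0.0, sigma, size=n) - 0.5 * sigma**2)

    # planted bias: biased pairs get a Normal(0, bias_sd) base value
    biased = rng.random(n) < cfg.bias_fraction
    base_bias = np.where(biased, rng.normal(0.0, cfg.bias_sd, size=n), 0.0)
    # ΔHEB pairs: bias shifts at one consecutive-condition boundary
    has_delta = rng.random(n) < cfg.delta_fraction
    delta_boundary = rng.integers(1, max(n_cond, 2), size=n)
    delta_sign = rng.choice([-1.0, 1.0], size=n)
    bias_by_cond = np.tile(base_bias[:, None], (1, n_cond))
    if n_cond > 1:
        for j in range(1, n_cond):
            shift = has_delta & (delta_boundary <= j)
            bias_by_cond[shift, j] += cfg.delta_shift * delta_sign[shift]

    freqs = np.array([cfg.pattern_frequencies.get(b, 0.0) for b in BINS])
    freqs = freqs / freqs.sum()
    bin_idx = rng.choice(len(BINS), size=(n, n_cond), p=freqs)
    hi_is_p1 = rng.random((n, n_cond)) < 0.5
    trans_parents_differ = rng.random((n, n_cond)) < 0.5

    sqf = np.sqrt(cfg.parental_fold)
    columns: dict[str, dict[str, np.ndarray]] = {"P1": {}, "P2": {}, "F1": {}}
    meta_rows = []
    truth_frames = []

    for j, cond in enumerate(cfg.conditions):
        bins_j = bin_idx[:, j]
        need_sep = np.isin(bins_j, [1, 2, 3]) | (
            np.isin(bins_j, [4, 5]) & trans_parents_differ[:, j]
        )
        hi = base_expr * sqf
        lo = base_expr / sqf
        mu1 = np.where(need_sep, np.where(hi_is_p1[:, j], hi, lo), base_expr)
        mu2 = np.where(need_sep, np.where(hi_is_p1[:, j], lo, hi), base_expr)

        hybrid = np.empty(n)
        hybrid[bins_j == 0] = base_expr[bins_j == 0]  # no_change
        m = bins_j == 1  # additivity: parental midpoint
        hybrid[m] = 0.5 * (mu1[m] + mu2[m])
        m = bins_j == 2  # ELD_P1: mimics parent 1
        hybrid[m] = mu1[m]
        m = bins_j == 3  # ELD_P2
        hybrid[m] = mu2[m]
        m = bins_j == 4  # transgressive_up
        hybrid[m] = cfg.transgressive_fold * np.maximum(mu1, mu2)[m]
        m = bins_j == 5  # transgressive_down
        hybrid[m] = np.minimum(mu1, mu2)[m] / cfg.transgressive_fold

        b = bias_by_cond[:, j]
        p1_share = np.exp2(b) / (1.0 + np.exp2(b))
        f1_spt_expr = hybrid * p1_share
        f1_spc_expr = hybrid * (1.0 - p1_share)

        for r in range(1, reps + 1):
            for taxon, means in (
                ("P1", {"own": mu1 * len_spt / 1000.0}),
                ("P2", {"own": mu2 * len_spc / 1000.0}),
                (
                    "F1",
                    {
                        "spt": f1_spt_expr * len_spt / 1000.0,
                        "spc": f1_spc_expr * len_spc / 1000.0,
                    },
                ),
            ):
                sample = f"{taxon}_{cond}_r{r}"
                if taxon == "F1":
                    columns["F1"][sample] = np.concatenate(
                        [
                            _draw_counts(rng, means["spt"], cfg.dispersion),
                            _draw_counts(rng, means["spc"], cfg.dispersion),
                        ]
                    )
                else:
                    columns[taxon][sample] = _draw_counts(
                        rng, means["own"], cfg.dispersion
                    )
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "taxon": taxon,
                        "condition": cond,
                        "replicate": r,
                    }
                )

        truth_frames.append(
            pd.DataFrame(
                {
                    "pair_id": pair_ids,
                    "p1_transcript": spt_ids,
                    "p2_transcript": spc_ids,
                    "condition": cond,
                    "bin": [BINS[k] for k in bins_j],
                    "true_b": b,
                    "p1_expr": mu1,
                    "p2_expr": mu2,
                    "hybrid_expr": hybrid,
                    "len_p1": len_spt,
                    "len_p2": len_spc,
                }
            )
        )

    counts_p1 = pd.DataFrame(columns["P1"], index=spt_ids)
    counts_p2 = pd.DataFrame(columns["P2"], index=spc_ids)
    counts_f1 = pd.DataFrame(
        columns["F1"], index=np.concatenate([spt_ids, spc_ids])
    )
    for df in (counts_p1, counts_p2, counts_f1):
        df.index.name = "transcript_id"
    lengths = pd.Series(
        np.concatenate([len_spt, len_spc]),
        index=np.concatenate([spt_ids, spc_ids]),
        name="length",
    )
    metadata = pd.DataFrame(meta_rows).drop_duplicates("sample_id")
    metadata = metadata.sort_values(
        ["taxon", "condition", "replicate"],
        key=lambda s: s.map({c: i for i, c in enumerate(cfg.conditions)})
        if s.name == "condition"
        else s,
    ).reset_index(drop=True)
    library_sizes = pd.Series(
        float(NOMINAL_LIBRARY_SIZE), index=metadata["sample_id"].to_numpy(),
        name="mapped_reads",
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    return SimResult(
        counts_p1=counts_p1,
        counts_p2=counts_p2,
        counts_f1=counts_f1,
        lengths=lengths,
        metadata=metadata,
        library_sizes=library_sizes,
        truth=truth,
        config=cfg,
    )


def _synthetic_hit_tables(
    sim: SimResult, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Alignment rows (12-column dialect) whose mutual best hits are the
    true pairs, plus weaker decoy and sub-threshold hits."""
    n = sim.config.n_pairs
    truth0 = sim.truth.drop_duplicates("pair_id")
    spt = truth0["p1_transcript"].to_numpy()
    spc = truth0["p2_transcript"].to_numpy()
    l1 = truth0["len_p1"].to_numpy()
    l2 = truth0["len_p2"].to_numpy()

    def row(q, s, pident, alen, evalue, bits):
        mism = int(round(alen * (100 - pident) / 100))
        return (
            f"{q}\t{s}\t{pident:.2f}\t{alen}\t{mism}\t0\t1\t{alen}\t1\t{alen}"
            f"\t{evalue:.2e}\t{bits:.1f}"
        )

    ab, ba = ["# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend\tsstart\tsend\tevalue\tbitscore"], []
    pident = 92.0 + 7.0 * rng.random(n)
    bits = 0.4 * np.minimum(l1, l2) + rng.normal(0, 5, n)
    for i in range(n):
        alen = int(min(l1[i], l2[i]))
        ab.append(row(spt[i], spc[i], pident[i], alen, 1e-180, bits[i]))
        ba.append(row(spc[i], spt[i], pident[i], alen, 1e-180, bits[i]))
        if i + 1 < n:
            # passes the filters but always loses best-hit to the true pair
            ab.append(row(spt[i], spc[i + 1], 90.5, alen, 1e-55, bits[i] * 0.6))
            # sub-threshold identity: removed by filtering
            ba.append(row(spc[i], spt[i - 1] if i else spt[n - 1], 80.0, alen,
                          1e-60, bits[i] * 0.9))
    return ab, ba


def write_fixture(sim: SimResult, directory: str | Path) -> dict[str, Path]:
    """Write the TSV fixture set consumed by the pipeline.

    Emits count matrices, lengths, metadata, library sizes, planted truth,
    synthetic alignment hit tables for the pairing stage, and a pipeline
    configuration (``config.yaml``) pointing at all of them.  Returns the
    path of every file written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.config.seed + 1_000_003)
    paths: dict[str, Path] = {}

    for name, df in (
        ("counts_P1", sim.counts_p1),
        ("counts_P2", sim.counts_p2),
        ("counts_F1", sim.counts_f1),
    ):
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p

    p = directory / "lengths.tsv"
    sim.lengths.rename_axis("transcript_id").to_csv(p, sep="\t")
    paths["lengths"] = p

    p = directory / "metadata.tsv"
    sim.metadata.to_csv(p, sep="\t", index=False)
    paths["metadata"] = p

    p = directory / "library_sizes.tsv"
    sim.library_sizes.rename_axis("sample_id").to_csv(p, sep="\t")
    paths["library_sizes"] = p

    p = directory / "truth.tsv"
    sim.truth.to_csv(p, sep="\t", index=False, float_format="%.10g")
    paths["truth"] = p

    ab, ba = _synthetic_hit_tables(sim, rng)
    for name, rows in (("hits_P1_vs_P2", ab), ("hits_P2_vs_P1", ba)):
        p = directory / f"{name}.tsv"
        p.write_text("\n".join(rows) + "\n")
        paths[name] = p

    # paths are written relative to the config file so fixtures are portable
    cfg = {
        "counts_p1": paths["counts_P1"].name,
        "counts_p2": paths["counts_P2"].name,
        "counts_f1": paths["counts_F1"].name,
        "lengths": paths["lengths"].name,
        "metadata": paths["metadata"].name,
        "library_sizes": paths["library_sizes"].name,
        "hits_p1_vs_p2": paths["hits_P1_vs_P2"].name,
        "hits_p2_vs_p1": paths["hits_P2_vs_P1"].name,
        "conditions": list(sim.config.conditions),
        "out_dir": "results",
    }
    p = directory / "config.yaml"
    with p.open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = p
    return paths
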