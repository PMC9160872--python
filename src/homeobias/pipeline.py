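"""End-to-end orchestration: pairing → normalization → ELD → HEB → ΔHEB.

Every stage writes a headered TSV into the configured output directory;
:func:`run_pipeline` returns the same tables in memory.  Exclusions
(unpaired transcripts, pairs failing the expression filter, zero-count
pairs) are tallied to the log so the denominator of every reported
percentage is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from homeobias import eld, heb, orthology, quant

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("homeobias")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    counts_p1: str
    counts_p2: str
    counts_f1: str
    lengths: str
    metadata: str
    out_dir: str
    conditions: list[str]
    hits_p1_vs_p2: str | None = None
    hits_p2_vs_p1: str | None = None
    pairs: str | None = None
    library_sizes: str | None = None
    min_identity: float = orthology.DEFAULT_MIN_IDENTITY
    max_evalue: float = orthology.DEFAULT_MAX_EVALUE
    min_tpm: float = 1.0
    min_samples: int = 1
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    delta_alpha: float = 0.05
    all_pairs: bool = False
    log2_transform: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pairs is None and (
            self.hits_p1_vs_p2 is None or self.hits_p2_vs_p1 is None
        ):
            raise ValueError(
                "either precomputed pairs or both directional hit tables "
                "are required"
            )
        for name in (
            "counts_p1", "counts_p2", "counts_f1", "lengths", "metadata",
            "hits_p1_vs_p2", "hits_p2_vs_p1", "pairs", "library_sizes",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if not self.conditions:
            raise ValueError("conditions must list the condition order")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; relative paths resolve against the file's directory."""
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in (
            "counts_p1", "counts_p2", "counts_f1", "lengths", "metadata",
            "hits_p1_vs_p2", "hits_p2_vs_p1", "pairs", "library_sizes",
            "out_dir",
        ):
            if raw.get(key) is not None:
                raw[key] = str(base / raw[key])
        return cls(**raw)


def _condition_samples(meta: pd.DataFrame, taxon: str, condition: str) -> list[str]:
    sel = meta[(meta["taxon"] == taxon) & (meta["condition"] == condition)]
    return list(sel.sort_values("replicate")["sample_id"])


def _stage_orthology(cfg: PipelineConfig, out: Path) -> list[orthology.HomeologPair]:
    if cfg.pairs is not None:
        pairs = orthology.read_pairs(cfg.pairs)
        log.info("orthology: loaded %d precomputed pairs", len(pairs))
        return pairs
    hits_ab = orthology.parse_hit_table(cfg.hits_p1_vs_p2)
    hits_ba = orthology.parse_hit_table(cfg.hits_p2_vs_p1)
    kept_ab = orthology.filter_hits(hits_ab, cfg.min_identity, cfg.max_evalue)
    kept_ba = orthology.filter_hits(hits_ba, cfg.min_identity, cfg.max_evalue)
    log.info(
        "orthology: %d/%d and %d/%d hits pass identity>=%g, evalue<=%g",
        len(kept_ab), len(hits_ab), len(kept_ba), len(hits_ba),
        cfg.min_identity, cfg.max_evalue,
    )
    pairs = orthology.reciprocal_best_hits(kept_ab, kept_ba)
    orthology.write_pairs(pairs, out / "pairs.tsv")
    log.info("orthology: %d reciprocal-best-hit pairs", len(pairs))
    return pairs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle as a dict of tables."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pairs = _stage_orthology(cfg, out)

    lengths = quant.read_lengths(cfg.lengths)
    meta = quant.read_metadata(cfg.metadata)
    missing_conds = set(meta["condition"]) - set(cfg.conditions)
    if missing_conds:
        raise ValueError(
            f"metadata conditions {sorted(missing_conds)} absent from the "
            "configured condition order"
        )
    libsizes = (
        quant.read_library_sizes(cfg.library_sizes)
        if cfg.library_sizes is not None
        else None
    )

    tables: dict[str, quant.ExpressionTable] = {}
    tpm: dict[str, quant.ExpressionTable] = {}
    rpkm: dict[str, quant.ExpressionTable] = {}
    expressed: dict[str, set[str]] = {}
    for taxon, path in (
        ("P1", cfg.counts_p1), ("P2", cfg.counts_p2), ("F1", cfg.counts_f1)
    ):
        tbl = quant.read_counts(path, lengths=lengths)
        sample_ids = [s for s in tbl.sample_ids]
        taxa_for_samples = meta.set_index("sample_id")["taxon"].reindex(sample_ids)
        if (taxa_for_samples != taxon).any():
            bad = list(taxa_for_samples.index[taxa_for_samples != taxon])
            raise ValueError(
                f"count matrix for {taxon} contains samples not labelled "
                f"{taxon} in metadata: {bad}"
            )
        if libsizes is not None:
            tbl.library_sizes = libsizes.reindex(tbl.values.columns)
        tables[taxon] = tbl
        tpm[taxon] = quant.compute_tpm(tbl)
        rpkm[taxon] = quant.compute_rpkm(tbl)
        expressed[taxon] = quant.filter_expressed(
            tpm[taxon], cfg.min_tpm, cfg.min_samples
        )
        log.info(
            "quant[%s]: %d/%d transcripts pass TPM>=%g in >=%d sample(s)",
            taxon, len(expressed[taxon]), len(tbl.transcript_ids),
            cfg.min_tpm, cfg.min_samples,
        )
        qc = quant.sample_correlation(tbl)
        qc.to_csv(out / f"qc_spearman_{taxon}.tsv", sep="\t", float_format="%.6g")

    f1_index = set(tables["F1"].transcript_ids)
    usable = []
    n_missing = n_unexpressed = 0
    for p in pairs:
        if p.p1_id not in f1_index or p.p2_id not in f1_index:
            n_missing += 1
            continue
        if p.p1_id not in expressed["F1"] or p.p2_id not in expressed["F1"]:
            n_unexpressed += 1
            continue
        usable.append(p)
    log.info(
        "pairs: %d detected in the hybrid (%d missing from the hybrid "
        "matrix, %d failed the expression filter)",
        len(usable), n_missing, n_unexpressed,
    )

    report: dict = {"pairs": pairs, "detected_pairs": usable}
    pair_ids = [f"{p.p1_id}|{p.p2_id}" for p in usable]
    p1_ids = [p.p1_id for p in usable]
    p2_ids = [p.p2_id for p in usable]

    # ---------------- ELD classification, per condition ----------------
    eld_tables: dict[str, pd.DataFrame] = {}
    eld_summary_rows = []
    for cond in cfg.conditions:
        f1_samples = _condition_samples(meta, "F1", cond)
        p1_samples = _condition_samples(meta, "P1", cond)
        p2_samples = _condition_samples(meta, "P2", cond)
        if min(len(f1_samples), len(p1_samples), len(p2_samples)) < 2:
            raise ValueError(
                f"condition {cond!r}: every taxon needs >= 2 replicates"
            )
        hyb = (
            rpkm["F1"].values.loc[p1_ids, f1_samples].to_numpy()
            + rpkm["F1"].values.loc[p2_ids, f1_samples].to_numpy()
        )
        par1 = rpkm["P1"].values.loc[p1_ids, p1_samples].to_numpy()
        par2 = rpkm["P2"].values.loc[p2_ids, p2_samples].to_numpy()
        calls = [
            eld.classify_pattern(
                hyb[i], par1[i], par2[i],
                alpha=cfg.alpha, log_transform=cfg.log2_transform,
            )
            for i in range(len(usable))
        ]
        df = pd.DataFrame(
            {
                "pair_id": pair_ids,
                "pattern": [c.pattern for c in calls],
                "bin": [c.bin for c in calls],
                "conflict_flag": [c.conflict_flag for c in calls],
                "p_h_vs_p1": [c.p_h_vs_p1 for c in calls],
                "p_h_vs_p2": [c.p_h_vs_p2 for c in calls],
                "p_p1_vs_p2": [c.p_p1_vs_p2 for c in calls],
                "mean_h": [c.mean_h for c in calls],
                "mean_p1": [c.mean_p1 for c in calls],
                "mean_p2": [c.mean_p2 for c in calls],
            }
        )
        df.to_csv(out / f"eld_{cond}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        eld_tables[cond] = df
        if calls:
            summ = eld.bin_patterns(calls)
            for b in eld.BINS:
                eld_summary_rows.append(
                    {"condition": cond, "kind": "bin", "label": b,
                     "count": int(summ.bin_counts[b]),
                     "proportion": float(summ.bin_proportions[b])}
                )
            for pat in eld.PATTERNS:
                eld_summary_rows.append(
                    {"condition": cond, "kind": "pattern", "label": pat,
                     "count": int(summ.pattern_counts[pat]),
                     "proportion": float(summ.pattern_proportions[pat])}
                )
    eld_summary = pd.DataFrame(eld_summary_rows)
    eld_summary.to_csv(out / "eld_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
    report["eld"] = eld_tables
    report["eld_summary"] = eld_summary

    # ---------------- HEB, per condition ----------------
    heb_tables: dict[str, pd.DataFrame] = {}
    heb_results: dict[str, list[heb.HEBResult]] = {}
    heb_summary_rows = []
    len_p1 = lengths.reindex(p1_ids).to_numpy(dtype=float)
    len_p2 = lengths.reindex(p2_ids).to_numpy(dtype=float)
    for cond in cfg.conditions:
        f1_samples = _condition_samples(meta, "F1", cond)
        cnt_spt = tables["F1"].values.loc[p1_ids, f1_samples].to_numpy()
        cnt_spc = tables["F1"].values.loc[p2_ids, f1_samples].to_numpy()
        rp_spt = rpkm["F1"].values.loc[p1_ids, f1_samples].to_numpy()
        rp_spc = rpkm["F1"].values.loc[p2_ids, f1_samples].to_numpy()
        x_spt = cnt_spt.sum(axis=1)
        x_spc = cnt_spc.sum(axis=1)
        testable = (x_spt > 0) & (x_spc > 0)
        log.info(
            "heb[%s]: %d/%d pairs testable (non-zero counts in both "
            "homeologs)", cond, int(testable.sum()), len(usable),
        )
        idx = np.flatnonzero(testable)
        b = np.log2(rp_spt[idx].mean(axis=1) / rp_spc[idx].mean(axis=1))
        lrt, p = heb.heb_lrt(x_spt[idx], x_spc[idx], len_p1[idx], len_p2[idx])
        results = [
            heb.HEBResult(
                pair_id=pair_ids[i], condition=cond,
                b=float(b[k]), lrt_stat=float(lrt[k]), p_value=float(p[k]),
            )
            for k, i in enumerate(idx)
        ]
        heb.apply_fdr(results, cfg.fdr_threshold)
        heb_results[cond] = results
        df = pd.DataFrame(
            {
                "pair_id": [r.pair_id for r in results],
                "b": [r.b for r in results],
                "lrt_stat": [r.lrt_stat for r in results],
                "p_value": [r.p_value for r in results],
                "q_value": [r.q_value for r in results],
                "significant": [r.significant for r in results],
                "direction": [r.direction for r in results],
            }
        )
        df.to_csv(out / f"heb_{cond}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        heb_tables[cond] = df
        if results:
            s = heb.summarize_bias(results, cfg.fdr_threshold)
            heb_summary_rows.append(
                {
                    "condition": cond,
                    "n_testable": s.n_testable,
                    "n_significant": s.n_significant,
                    "n_toward_p1": s.n_toward_p1,
                    "n_toward_p2": s.n_toward_p2,
                    "mean_b_toward_p1": s.mean_b_toward_p1,
                    "fold_toward_p1": s.fold_toward_p1,
                    "mean_b_toward_p2": s.mean_b_toward_p2,
                    "fold_toward_p2": s.fold_toward_p2,
                    "overall_mean_b": s.overall_mean_b,
                    "pct_biased": s.pct_biased,
                }
            )
    heb_summary = pd.DataFrame(heb_summary_rows)
    heb_summary.to_csv(out / "heb_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
    report["heb"] = heb_tables
    report["heb_results"] = heb_results
    report["heb_summary"] = heb_summary

    # ---------------- ΔHEB between conditions ----------------
    if cfg.all_pairs:
        contrasts = [
            (a, b2)
            for i, a in enumerate(cfg.conditions)
            for b2 in cfg.conditions[i + 1:]
        ]
    else:
        contrasts = list(zip(cfg.conditions, cfg.conditions[1:]))

    delta_tables: dict[tuple[str, str], pd.DataFrame] = {}
    delta_summary_rows = []
    for c1, c2 in contrasts:
        t1 = heb_tables[c1].set_index("pair_id")
        t2 = heb_tables[c2].set_index("pair_id")
        common = t1.index.intersection(t2.index)
        log.info("delta_heb[%s vs %s]: %d pairs testable in both", c2, c1,
                 len(common))
        s1 = _condition_samples(meta, "F1", c1)
        s2 = _condition_samples(meta, "F1", c2)
        cpos = {pid: i for i, pid in enumerate(pair_ids)}
        rows = [cpos[pid] for pid in common]
        x1s = tables["F1"].values.loc[[p1_ids[i] for i in rows], s1].to_numpy().sum(axis=1)
        x1c = tables["F1"].values.loc[[p2_ids[i] for i in rows], s1].to_numpy().sum(axis=1)
        x2s = tables["F1"].values.loc[[p1_ids[i] for i in rows], s2].to_numpy().sum(axis=1)
        x2c = tables["F1"].values.loc[[p2_ids[i] for i in rows], s2].to_numpy().sum(axis=1)
        b1 = t1.loc[common, "b"].to_numpy()
        b2v = t2.loc[common, "b"].to_numpy()
        delta = b2v - b1
        if len(common):
            lrt, p = heb.delta_heb_lrt(x1s, x1c, x2s, x2c)
        else:
            lrt = p = np.array([])
        sig = p < cfg.delta_alpha
        direction = np.where(
            sig, np.where(delta > 0, "toward_P1", "toward_P2"), "none"
        )
        df = pd.DataFrame(
            {
                "pair_id": common,
                "b1": b1,
                "b2": b2v,
                "delta": delta,
                "lrt_stat": lrt,
                "p_value": p,
                "significant": sig,
                "direction": direction,
            }
        )
        df.to_csv(out / f"delta_heb_{c1}_vs_{c2}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        delta_tables[(c1, c2)] = df
        for dname, mask in (
            ("toward_P1", sig & (delta > 0)),
            ("toward_P2", sig & (delta < 0)),
        ):
            delta_summary_rows.append(
                {
                    "condition_1": c1,
                    "condition_2": c2,
                    "direction": dname,
                    "n_testable": len(common),
                    "n_significant": int(sig.sum()),
                    "n_direction": int(mask.sum()),
                    "mean_delta": float(delta[mask].mean()) if mask.any() else np.nan,
                    "fold": float(np.exp2(abs(delta[mask].mean())))
                    if mask.any() else np.nan,
                }
            )
    delta_summary = pd.DataFrame(delta_summary_rows)
    delta_summary.to_csv(out / "delta_heb_summary.tsv", sep="\t", index=False,
                         float_format="%.6g")
    report["delta_heb"] = delta_tables
    report["delta_heb_summary"] = delta_summary
    log.info("pipeline complete; outputs in %s", out)
    return report
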