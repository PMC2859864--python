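"""Summary tables, Fisher's exact frequency comparisons and accounting.

The report bundle mirrors what a full-length cDNA resource paper tabulates:
length summaries (insert, CDS, UTRs), nucleotide composition per region,
stop-codon usage, exon/intron statistics, splice-event class proportions
and the SNP estimate, together with the stage-by-stage accounting ledger
whose conservation identities (in = removed + kept, chained between
stages) are checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_utr import composition, length_summary, stop_codon_usage
from .io_formats import write_table


@dataclass
class LedgerStage:
    name: str
    n_in: int
    n_removed: int
    n_kept: int


class LedgerViolation(ValueError):
    pass


def pipeline_accounting(stages: Sequence[LedgerStage | tuple]) -> list[LedgerStage]:
    """Validate conservation identities of an ordered accounting ledger.

    Checks in = removed + kept per stage and kept[i] = in[i+1] between
    stages; raises :class:`LedgerViolation` naming the failing stage.
    """
    rows = [s if isinstance(s, LedgerStage) else LedgerStage(*s)
            for s in stages]
    for row in rows:
        if row.n_in != row.n_removed + row.n_kept:
            raise LedgerViolation(
                f"stage {row.name!r}: {row.n_in} != "
                f"{row.n_removed} + {row.n_kept}")
    for a, b in zip(rows, rows[1:]):
        if a.n_kept != b.n_in:
            raise LedgerViolation(
                f"stage {b.name!r}: carries {b.n_in} in but previous stage "
                f"kept {a.n_kept}")
    return rows


def fisher_category_test(counts: dict[str, tuple[int, int]],
                         total_set: int, total_ref: int,
                         alpha: float = 0.01,
                         correct: bool = False) -> pd.DataFrame:
    """Two-sided Fisher's exact test per category.

    ``counts`` maps category -> (count in the study set, count in the
    reference set); each 2x2 table is (in/not-in category) x (set/
    reference).  No multiplicity correction by default; ``correct`` enables
    Benjamini-Hochberg.
    """
    if total_set <= 0 or total_ref <= 0:
        raise ValueError("totals must be positive")
    rows = []
    for cat in sorted(counts):
        a, b = counts[cat]
        if a > total_set or b > total_ref or a < 0 or b < 0:
            raise ValueError(f"category {cat!r}: counts exceed totals")
        table = [[a, total_set - a], [b, total_ref - b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(dict(category=cat, count_set=a, count_ref=b,
                         freq_set=a / total_set, freq_ref=b / total_ref,
                         p_value=float(p)))
    df = pd.DataFrame(rows)
    if correct and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(order[::-1]):
            running = min(running,
                          df["p_value"].iloc[idx] * m / (m - rank))
            adj[idx] = running
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def histogram_rows(values: Sequence[float], bin_width: float) -> list[dict]:
    """(bin_start, count) rows for TSV export."""
    if len(values) == 0:
        return []
    arr = np.asarray(values, dtype=float)
    lo = 0.0
    hi = float(arr.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    return [dict(bin_start=float(e), count=int(c))
            for e, c in zip(edges[:-1], counts) if c or True]


def build_report(outdir,
                 *,
                 cds_results=None,
                 ledger: Sequence[LedgerStage] | None = None,
                 genome_stats: dict | None = None,
                 event_counts: dict[str, int] | None = None,
                 snp=None,
                 utr_occurrence: tuple[float, float] | None = None) -> dict:
    """Assemble the report bundle: TSVs in ``outdir`` plus a JSON summary.

    Stages that did not run are reported as explicit gaps.  Every number is
    recomputed here from the per-sequence results passed in; the JSON is
    byte-stable for a fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"missing_stages": []}

    if cds_results:
        full = [r for r in cds_results
                if r.annotation.completeness == "full_length"]
        lengths = {
            "insert": [len(r.body) + (r.polya_interval[1]
                                      - r.polya_interval[0])
                       for r in cds_results],
            "cds": [r.annotation.cds_interval[1] - r.annotation.cds_interval[0]
                    for r in full],
            "utr5": [r.utrs.utr5_len for r in full],
            "utr3": [r.utrs.utr3_len for r in full],
        }
        length_rows = []
        for name, vals in lengths.items():
            if vals:
                mean, median = length_summary(vals)
                length_rows.append(dict(feature=name, n=len(vals),
                                        mean=mean, median=median))
        write_table(length_rows, outdir / "length_summary.tsv")
        summary["lengths"] = {r["feature"]: {"mean": r["mean"],
                                             "median": r["median"],
                                             "n": r["n"]}
                              for r in length_rows}

        regions = {
            "full_length": [r.body for r in full],
            "utr5": [r.body[:r.annotation.cds_interval[0]] for r in full],
            "cds": [r.body[slice(*r.annotation.cds_interval)] for r in full],
            "utr3": [r.body[r.annotation.cds_interval[1]:] for r in full],
        }
        comp_rows = []
        for name, seqs in regions.items():
            comp = composition(seqs)
            comp_rows.append(dict(region=name, **{k: round(v, 4)
                                                  for k, v in comp.items()}))
        write_table(comp_rows, outdir / "composition.tsv")
        summary["composition"] = {r["region"]: r for r in comp_rows}

        stops = [r.stop_codon for r in full if r.stop_codon]
        usage = stop_codon_usage(stops)
        write_table([dict(codon=c, percent=round(p, 4))
                     for c, p in usage.items()],
                    outdir / "stop_codon_usage.tsv")
        summary["stop_codon_usage"] = usage
        summary["completeness"] = {
            "full_length": len(full),
            "partial": sum(r.annotation.completeness == "partial"
                           for r in cds_results),
            "none": sum(r.annotation.completeness == "none"
                        for r in cds_results)}
        for name, width in (("insert", 100), ("cds", 100),
                            ("utr5", 25), ("utr3", 25)):
            rows = histogram_rows(lengths[name], width)
            write_table(rows, outdir / f"hist_{name}.tsv")
    else:
        summary["missing_stages"].append("cds")

    if ledger is not None:
        rows = pipeline_accounting(ledger)
        write_table([vars(r) for r in rows], outdir / "ledger.tsv")
        summary["ledger"] = [vars(r) for r in rows]
    else:
        summary["missing_stages"].append("curation")

    if genome_stats is not None:
        write_table([genome_stats], outdir / "exon_intron_stats.tsv")
        summary["genome"] = genome_stats
    else:
        summary["missing_stages"].append("mapping")

    if utr_occurrence is not None:
        summary["utr_intron_occurrence"] = {
            "start_in_internal_exon": utr_occurrence[0],
            "stop_in_internal_exon": utr_occurrence[1]}

    if event_counts is not None:
        total = sum(event_counts.values())
        rows = [dict(type=t, count=c,
                     percent=(100.0 * c / total if total else 0.0))
                for t, c in sorted(event_counts.items())]
        write_table(rows, outdir / "splice_events.tsv")
        summary["splice_events"] = {r["type"]: r["percent"] for r in rows}
        summary["splice_event_total"] = total
    else:
        summary["missing_stages"].append("splice")

    if snp is not None:
        write_table([dict(pairs_used=snp.pairs_used,
                          mismatches=snp.mismatches,
                          aligned_exon_bases=snp.aligned_exon_bases,
                          rate_percent=snp.rate_percent)],
                    outdir / "snp.tsv")
        summary["snp"] = {"pairs_used": snp.pairs_used,
                          "mismatches": snp.mismatches,
                          "aligned_exon_bases": snp.aligned_exon_bases,
                          "rate_percent": snp.rate_percent}
    else:
        summary["missing_stages"].append("snp")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
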