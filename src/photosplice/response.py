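"""Light-responsiveness testing, ranking and IR quantification.

Each filtered event is tested with a 2 x k chi-square homogeneity test
comparing supporting vs non-supporting read counts across the k conditions
of one group (dark baseline plus the light timepoints).  Events are called
significant at a raw P < 0.001 by default; no continuity correction is
applied and Benjamini-Hochberg q-values are emitted as an extra column for
users but play no role in the replication-mode significance call.

For IR events the retention level is expressed as IPKM (intron reads per
kilobase of retained intron per million mapped reads) normalized by the
gene's RPKM, and as the relative IR level: the IPKM/RPKM ratio of each
condition divided by the ratio in the dark-grown baseline.

An alternative goodness-of-fit mode tests each light condition against
expected proportions taken from the baseline; the homogeneity test is the
default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel, derive_introns
from .counting import CountTables, ipkm, rpkm
from .events import ASEvent

log = logging.getLogger(__name__)

__all__ = [
    "UntestableTableError",
    "LightResponseResult",
    "chi_square_homogeneity",
    "chi_square_gof_vs_baseline",
    "test_all_events",
    "rank_top_events",
    "relative_ir",
    "mean_normalize_profile",
    "attach_ir_quantification",
    "write_results_tsv",
    "write_normalized_matrix",
]

DEFAULT_ALPHA = 1e-3


class UntestableTableError(ValueError):
    """The contingency table has a degenerate margin (zero row or column)."""


def chi_square_homogeneity(
    supporting: Sequence[int], nonsupporting: Sequence[int]
) -> tuple[float, int, float]:
    """Chi-square homogeneity test on a 2 x k supporting/non-supporting table.

    Returns ``(chi2, df, p)`` with ``chi2 = sum (O-E)^2/E`` over all cells,
    ``E = row_total * col_total / grand_total`` and ``df = k - 1``.
    Degenerate margins raise :class:`UntestableTableError`.
    """
    observed = np.asarray([supporting, nonsupporting], dtype=float)
    if observed.ndim != 2 or observed.shape[1] < 2:
        raise ValueError("need counts for at least two conditions")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    row_totals = observed.sum(axis=1)
    col_totals = observed.sum(axis=0)
    if (row_totals == 0).any() or (col_totals == 0).any():
        raise UntestableTableError("zero row or column margin")
    grand = observed.sum()
    expected = np.outer(row_totals, col_totals) / grand
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = observed.shape[1] - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def chi_square_gof_vs_baseline(
    supporting: Sequence[int],
    nonsupporting: Sequence[int],
    baseline_index: int = 0,
) -> tuple[float, int, float]:
    """Goodness-of-fit variant: test the non-baseline columns against the
    supporting fraction observed in the baseline condition."""
    sup = np.asarray(supporting, dtype=float)
    non = np.asarray(nonsupporting, dtype=float)
    n0 = sup[baseline_index] + non[baseline_index]
    if n0 == 0 or sup[baseline_index] == 0:
        raise UntestableTableError("baseline margin is degenerate")
    p0 = sup[baseline_index] / n0
    chi2 = 0.0
    df = 0
    for c in range(len(sup)):
        if c == baseline_index:
            continue
        n_c = sup[c] + non[c]
        if n_c == 0:
            continue
        e_sup, e_non = n_c * p0, n_c * (1 - p0)
        chi2 += (sup[c] - e_sup) ** 2 / e_sup
        if e_non > 0:
            chi2 += (non[c] - e_non) ** 2 / e_non
        df += 1
    if df == 0:
        raise UntestableTableError("no testable non-baseline condition")
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


@dataclass
class LightResponseResult:
    """Test outcome and quantification for one event."""

    event: ASEvent
    testable: bool
    chi2: float = math.nan
    df: int = 0
    p_value: float = math.nan
    significant: bool = False
    q_value: float = math.nan
    rank: int | None = None
    ipkm_series: tuple[float, ...] | None = None
    rpkm_series: tuple[float, ...] | None = None
    relative_ir: tuple[float, ...] | None = None


def test_all_events(
    events: Iterable[ASEvent],
    alpha: float = DEFAULT_ALPHA,
    method: str = "homogeneity",
) -> list[LightResponseResult]:
    """Test every event; untestable tables are flagged and excluded from
    ranking rather than assigned p = 1."""
    if method == "homogeneity":
        testfun = chi_square_homogeneity
    elif method == "gof_vs_baseline":
        testfun = chi_square_gof_vs_baseline
    else:
        raise ValueError(f"unknown test method {method!r}")
    results = []
    for event in events:
        try:
            chi2, df, p = testfun(event.supporting, event.nonsupporting)
        except UntestableTableError:
            results.append(LightResponseResult(event=event, testable=False))
            continue
        results.append(
            LightResponseResult(
                event=event,
                testable=True,
                chi2=chi2,
                df=df,
                p_value=p,
                significant=p < alpha,
            )
        )
    testable = [r for r in results if r.testable]
    if testable:
        qs = stats.false_discovery_control([r.p_value for r in testable])
        for r, q in zip(testable, qs):
            r.q_value = float(q)
    return results


def _rank_key(result: LightResponseResult):
    return (result.p_value, -result.chi2, result.event.gene_id, result.event.locus)


def rank_top_events(
    results: Iterable[LightResponseResult], k: int
) -> list[LightResponseResult]:
    """Rank testable results by ascending p, then descending chi2, then
    (gene_id, locus); assign ranks and return the top ``k``."""
    testable = sorted((r for r in results if r.testable), key=_rank_key)
    for i, r in enumerate(testable, start=1):
        r.rank = i
    if k > len(testable):
        log.info("requested top %d of %d tested events", k, len(testable))
    return testable[: max(k, 0)]


def relative_ir(
    ipkm_series: Sequence[float],
    rpkm_series: Sequence[float],
    baseline_index: int = 0,
) -> tuple[float, ...]:
    """Per-condition IR level relative to the baseline condition.

    ``value_c = (ipkm_c / rpkm_c) / (ipkm_b / rpkm_b)``; the baseline value
    is exactly 1 whenever defined.  A zero or undefined baseline ratio
    makes every value missing (NaN); a zero ``rpkm_c`` makes that
    condition's value missing.
    """
    ratios = []
    for i_val, r_val in zip(ipkm_series, rpkm_series):
        ratios.append(i_val / r_val if r_val > 0 else math.nan)
    base = ratios[baseline_index]
    if not (base > 0):  # 0 or NaN
        return tuple(math.nan for _ in ratios)
    return tuple(r / base if not math.isnan(r) else math.nan for r in ratios)


def mean_normalize_profile(values: Sequence[float]) -> tuple[float, ...]:
    """Divide a per-condition profile by its mean (mean must be > 0)."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if not mean > 0:
        raise ValueError("profile mean must be > 0")
    return tuple(float(v) for v in arr / mean)


def attach_ir_quantification(
    results: Iterable[LightResponseResult],
    tables_by_sample: Mapping[str, CountTables],
    genes: Sequence[GeneModel],
    baseline_index: int = 0,
) -> None:
    """Fill IPKM/RPKM series and relative IR for IR-event results in place."""
    genes_by_id = {g.gene_id: g for g in genes}
    intron_lengths = {
        (g.gene_id, intr.int_no): intr.length
        for g in genes
        for intr in derive_introns(g)
    }
    tables = list(tables_by_sample.values())
    for r in results:
        e = r.event
        if e.kind != "IR" or e.gene_id not in genes_by_id:
            continue
        gene = genes_by_id[e.gene_id]
        l_intron = intron_lengths[(e.gene_id, e.locus[0])]
        ipkms, rpkms = [], []
        for t in tables:
            n = t.total_mapped
            if n <= 0:
                ipkms.append(math.nan)
                rpkms.append(math.nan)
                continue
            ipkms.append(ipkm(t.intron_counts.get((e.gene_id, e.locus[0]), 0), n, l_intron))
            rpkms.append(rpkm(t.gene_exon_reads(e.gene_id), n, gene.exon_model_length))
        r.ipkm_series = tuple(ipkms)
        r.rpkm_series = tuple(rpkms)
        r.relative_ir = relative_ir(ipkms, rpkms, baseline_index)


# ---------------------------------------------------------------------------
# serialization


def _fmt_series(series: tuple[float, ...] | None) -> str:
    if series is None:
        return ""
    return ",".join(format(v, ".6g") for v in series)


def write_results_tsv(
    results: Sequence[LightResponseResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "kind\tgene_id\tlocus\ttestable\tchi2\tdf\tp_value\tq_value\t"
            "significant\trank\tipkm\trpkm\trelative_ir\n"
        )
        for r in results:
            e = r.event
            fh.write(
                "\t".join(
                    [
                        e.kind,
                        e.gene_id,
                        ",".join(map(str, e.locus)),
                        str(int(r.testable)),
                        format(r.chi2, ".6g"),
                        str(r.df),
                        format(r.p_value, ".6g"),
                        format(r.q_value, ".6g"),
                        str(int(r.significant)),
                        "" if r.rank is None else str(r.rank),
                        _fmt_series(r.ipkm_series),
                        _fmt_series(r.rpkm_series),
                        _fmt_series(r.relative_ir),
                    ]
                )
                + "\n"
            )


def write_normalized_matrix(
    results: Sequence[LightResponseResult],
    samples: Sequence[str],
    path: str | Path,
) -> int:
    """Mean-normalized IR and gene-expression profiles as a matrix TSV.

    Rows whose profile mean is zero are excluded (and counted in the
    return value's complement); returns the number of rows written.
    """
    written = 0
    with open(path, "w") as fh:
        header = ["kind", "gene_id", "locus", "profile"]
        header += [f"{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for r in results:
            if r.ipkm_series is None:
                continue
            for label, series in (("IR", r.ipkm_series), ("gene", r.rpkm_series)):
                try:
                    norm = mean_normalize_profile(series)
                except ValueError:
                    log.info(
                        "zero-mean %s profile for %s excluded", label, r.event.key
                    )
                    continue
                fh.write(
                    "\t".join(
                        [
                            r.event.kind,
                            r.event.gene_id,
                            ",".join(map(str, r.event.locus)),
                            label,
                        ]
                        + [format(v, ".6g") for v in norm]
                    )
                    + "\n"
                )
                written += 1
    return written
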