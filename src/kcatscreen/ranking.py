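"""Per-locus winner selection, combinatorial variant proposal, reporting.

After screening, the surviving mutation(s) with the highest combined kcat
at each scanned locus are selected; exact kcat ties at a locus return all
tied mutations (a locus can legitimately carry two winners). Multi-point
variants are then proposed as all 2..max_order subsets of the per-locus
winners. Experimental triage normally sits between the two steps: the
combinations worth building are chosen from the winners that validate at
the bench, so ``propose_combinations`` takes an explicit winner list.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .ensemble import CalibrationResult
from .predictors import PredictionTable
from .screen import FilterVerdict, ScreenConfig
from .sequence import Mutation, Variant

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedCandidate:
    mutation: Mutation
    combined_kcat: float
    rank_overall: int     # dense rank among winners, 1 = best
    rank_in_site: int
    verdict: FilterVerdict


def select_per_site_best(combined: PredictionTable,
                         verdicts: list[FilterVerdict],
                         ) -> list[RankedCandidate]:
    """Per locus, the surviving mutation(s) of maximal combined kcat.

    Only mutations whose verdict passed are eligible; exact ties at a
    locus all win (``rank_in_site`` 1 for each). Loci where every
    mutation failed screening are omitted with a log message. A verdict
    whose mutation has no prediction is an error.
    """
    for v in verdicts:
        if str(v.mutation) not in combined:
            raise ValueError(
                f"mutation {v.mutation} has a verdict but no prediction")
    survivors = [v for v in verdicts if v.passed]
    by_site: dict[int, list[FilterVerdict]] = {}
    for v in survivors:
        by_site.setdefault(v.mutation.position, []).append(v)
    all_sites = {v.mutation.position for v in verdicts}
    for site in sorted(all_sites - set(by_site)):
        log.info("site %d: no surviving mutations; omitted", site)

    winners: list[tuple[FilterVerdict, float]] = []
    for site in sorted(by_site):
        site_verdicts = by_site[site]
        best = max(combined[str(v.mutation)] for v in site_verdicts)
        tied = [v for v in site_verdicts
                if combined[str(v.mutation)] == best]
        winners.extend((v, best) for v in tied)

    # dense overall rank by descending kcat
    distinct = sorted({k for _, k in winners}, reverse=True)
    rank_of = {k: i + 1 for i, k in enumerate(distinct)}
    out = [RankedCandidate(mutation=v.mutation, combined_kcat=k,
                           rank_overall=rank_of[k], rank_in_site=1,
                           verdict=v)
           for v, k in winners]
    out.sort(key=lambda c: (c.rank_overall, c.mutation.position,
                            c.mutation.mut_aa))
    return out


def propose_combinations(winners: list[Mutation],
                         max_order: int) -> list[Variant]:
    """All multi-point variants buildable from per-site winners.

    Subsets of size 2..min(max_order, #winners), in lexicographic order
    by position tuple — e.g. three winners at distinct loci with
    ``max_order=3`` give exactly three doubles and one triple. Two
    winners at the same position are an error: ties must be disambiguated
    by the caller first.
    """
    if max_order < 2:
        raise ValueError(f"max_order must be >= 2, got {max_order}")
    positions = [m.position for m in winners]
    if len(positions) != len(set(positions)):
        raise ValueError("two winners share a position; resolve the tie "
                         "before proposing combinations")
    ordered = sorted(winners, key=lambda m: m.position)
    out: list[Variant] = []
    for size in range(2, min(max_order, len(ordered)) + 1):
        for subset in itertools.combinations(ordered, size):
            out.append(Variant.from_mutations(subset))
    return out


def break_ties(candidates: list[RankedCandidate],
               policy: str = "error") -> list[Mutation]:
    """Reduce ranked winners to one mutation per site.

    ``policy='alphabetical'`` keeps the alphabetically first substituting
    residue among exact ties; ``'error'`` (default) refuses, so silent
    divergence from user intent is impossible.
    """
    by_site: dict[int, list[RankedCandidate]] = {}
    for c in candidates:
        by_site.setdefault(c.mutation.position, []).append(c)
    out = []
    for site in sorted(by_site):
        tied = sorted(by_site[site], key=lambda c: c.mutation.mut_aa)
        if len(tied) > 1 and policy == "error":
            raise ValueError(
                f"site {site} has {len(tied)} tied winners "
                f"({', '.join(str(c.mutation) for c in tied)}); "
                f"use tie-break policy 'alphabetical' or disambiguate")
        out.append(tied[0].mutation)
    return out


def generate_report(candidates: list[RankedCandidate],
                    combos: list[Variant], out_dir,
                    config: ScreenConfig | None = None,
                    calibration: CalibrationResult | None = None,
                    all_verdicts: list[FilterVerdict] | None = None,
                    ) -> dict[str, Path]:
    """Write the ranked-candidate TSV and a human-readable summary.

    Outputs are byte-stable for identical inputs (no timestamps). The
    ranked TSV keeps its header even with zero survivors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranked_path = out_dir / "ranked_candidates.tsv"
    summary_path = out_dir / "summary.txt"

    header_lines = []
    if config is not None:
        for k, v in sorted(config.to_dict().items()):
            header_lines.append(f"# {k}={v}")
    if calibration is not None:
        header_lines.append(
            f"# calibration: mode={calibration.mode} "
            f"factor={calibration.factor:.6g} k1_wt={calibration.k1_wt:.6g} "
            f"k2_wt={calibration.k2_wt:.6g}")
    rows = ["\t".join(["mutation", "combined_kcat", "rank_overall",
                       "rank_in_site", "passed", "reasons",
                       "diagnostics_json"])]
    for c in candidates:
        rows.append("\t".join([
            str(c.mutation), f"{c.combined_kcat:.6g}",
            str(c.rank_overall), str(c.rank_in_site),
            str(c.verdict.passed).lower(), ",".join(c.verdict.reasons),
            json.dumps(c.verdict.diagnostics, sort_keys=True),
        ]))
    ranked_path.write_text("\n".join(header_lines + rows) + "\n")

    reason_counts: dict[str, int] = {}
    n_screened = n_failed = 0
    if all_verdicts:
        n_screened = len(all_verdicts)
        n_failed = sum(not v.passed for v in all_verdicts)
        for v in all_verdicts:
            for r in v.reasons:
                reason_counts[r] = reason_counts.get(r, 0) + 1
    summary = ["screening summary", "================="]
    summary.append(f"mutations screened: {n_screened}")
    summary.append(f"mutations excluded: {n_failed}")
    for r in sorted(reason_counts):
        summary.append(f"  {r}: {reason_counts[r]}")
    summary.append(f"site winners: {len(candidates)}")
    summary.append(f"proposed combinations: {len(combos)}")
    for v in combos:
        summary.append(f"  {v.label}")
    if calibration is not None:
        summary.append(
            f"calibration factor: {calibration.factor:.6g} "
            f"(k1_wt={calibration.k1_wt:.6g}, k2_wt={calibration.k2_wt:.6g}, "
            f"mode={calibration.mode})")
    if config is not None:
        summary.append("thresholds:")
        for k, v in sorted(config.to_dict().items()):
            summary.append(f"  {k}: {v}")
    summary_path.write_text("\n".join(summary) + "\n")
    return {"ranked": ranked_path, "summary": summary_path}
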