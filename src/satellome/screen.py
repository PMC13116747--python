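"""Contaminant screening cascade.

Candidates derived from protein-coding genes, transposable elements,
organellar genomes or rDNA are removed before a candidate becomes a
satellite family.  The cascade order is fixed: coding -> TE ->
organelle/rDNA; a candidate is removed for exactly one (the first
matching) reason.

The coding screen is a translated-similarity stand-in: all six reading
frames of the candidate are aligned against each reference protein, and
the candidate is removed when any frame covers >= 50% of a protein at
E <= 1e-5.  The TE screen is a plain nucleotide similarity search at
E <= 1e-3.  The organelle/rDNA screen removes a candidate when hits at
E <= 0.01 to a single reference jointly cover >= 80% of the candidate
(coverage on the merged union of hit intervals, since fragmented hits are
the norm)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .align import (
    AlignmentHit,
    AlignmentParams,
    HitThresholds,
    estimate_evalue,
    local_align,
    local_align_protein,
    revcomp,
    scan_hits,
)
from .detect import ConsensusCandidate

SCREEN_ORDER = ("coding", "te", "organelle_rdna")


@dataclass
class ScreenResult:
    candidate_id: str
    screen: str
    best_hit: Optional[AlignmentHit]
    removed: bool
    reason: str = ""


def _six_frames(seq: str) -> list[tuple[int, str]]:
    frames = []
    for strand_seq in (seq, revcomp(seq)):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                frames.append((off, str(Seq(sub).translate())))
    return frames


def screen_coding(
    candidates: Sequence[ConsensusCandidate],
    protein_refs: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    max_evalue: float = 1e-5,
    min_protein_coverage_pct: float = 50.0,
) -> list[ScreenResult]:
    """Remove candidates one of whose reading frames aligns to a reference
    protein over at least half the protein's length at E <= 1e-5."""
    if protein_refs is None:
        protein_refs = []
    results = []
    for cand in candidates:
        best: Optional[AlignmentHit] = None
        removed = False
        reason = ""
        # the consensus of a tandem unit is rotation-ambiguous; translating
        # the doubled sequence keeps an ORF split across the junction intact
        doubled = cand.sequence + cand.sequence
        for ref_name, prot in protein_refs:
            for off, frame in _six_frames(doubled):
                if len(frame.replace("*", "")) < 10:
                    continue
                res = local_align_protein(prot, frame, params)
                if res is None:
                    continue
                score, qs, qe, ss, se, ident = res
                cov = 100.0 * (qe - qs + 1) / len(prot)
                ev = estimate_evalue(score, len(prot), len(frame), params)
                if ev <= max_evalue and cov >= min_protein_coverage_pct:
                    removed = True
                    reason = f"frame matches protein {ref_name} ({cov:.0f}% of protein, E={ev:.1e})"
                    best = AlignmentHit(
                        query_id=cand.candidate_id, subject_id=ref_name,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se, strand="+",
                        identity_pct=min(100.0, ident), query_coverage_pct=min(100.0, cov),
                        score=score, evalue=ev,
                    )
                    break
            if removed:
                break
        results.append(ScreenResult(cand.candidate_id, "coding", best, removed, reason))
    return results


def screen_te(
    candidates: Sequence[ConsensusCandidate],
    te_refs: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    max_evalue: float = 1e-3,
) -> list[ScreenResult]:
    """Remove candidates with any nucleotide hit to a TE reference at
    E <= 1e-3 (stand-in for profile-HMM scanning)."""
    results = []
    for cand in candidates:
        best = None
        removed = False
        reason = ""
        for ref_name, ref_seq in te_refs or []:
            hit = local_align(cand.sequence, ref_seq, params,
                              query_id=cand.candidate_id, subject_id=ref_name)
            if hit is not None and hit.evalue <= max_evalue:
                removed = True
                reason = f"nucleotide hit to TE {ref_name} (E={hit.evalue:.1e})"
                best = hit
                break
        results.append(ScreenResult(cand.candidate_id, "te", best, removed, reason))
    return results


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = 0
    for s, e in sorted(intervals):
        if e <= end:
            continue
        total += e - max(s, end + 1) + 1
        end = e
    return total


def screen_organelle_rdna(
    candidates: Sequence[ConsensusCandidate],
    refs: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    max_evalue: float = 0.01,
    min_coverage_pct: float = 80.0,
) -> list[ScreenResult]:
    """Remove candidates whose hits (E <= 0.01) to a single organelle or
    rDNA reference jointly cover >= 80% of the candidate."""
    loose = HitThresholds(max_evalue=max_evalue, min_identity_pct=0.0,
                          min_query_coverage_pct=0.0)
    results = []
    for cand in candidates:
        best = None
        removed = False
        reason = ""
        for ref_name, ref_seq in refs or []:
            hits = scan_hits(cand.sequence, ref_seq, params, loose,
                             query_id=cand.candidate_id, subject_id=ref_name)
            if not hits:
                continue
            cov = 100.0 * _union_len([(h.q_start, h.q_end) for h in hits]) / len(cand.sequence)
            top = max(hits, key=lambda h: h.score)
            if best is None or top.score > best.score:
                best = top
            if cov >= min_coverage_pct:
                removed = True
                reason = f"{cov:.0f}% of candidate covered by {ref_name}"
                best = top
                break
        results.append(
            ScreenResult(cand.candidate_id, "organelle_rdna", best if removed else best,
                         removed, reason)
        )
    return results


def run_screens(
    candidates: Sequence[ConsensusCandidate],
    protein_refs: Sequence[tuple[str, str]] = (),
    te_refs: Sequence[tuple[str, str]] = (),
    organelle_rdna_refs: Sequence[tuple[str, str]] = (),
    params: AlignmentParams = AlignmentParams(),
) -> tuple[list[ConsensusCandidate], list[ScreenResult]]:
    """Full cascade in the fixed order coding -> TE -> organelle/rDNA.
    Returns (retained candidates, all screen results).  A removed candidate
    carries exactly one removal record (its first matching screen)."""
    remaining = list(candidates)
    log: list[ScreenResult] = []
    for screen_name, refs, fn in (
        ("coding", protein_refs, screen_coding),
        ("te", te_refs, screen_te),
        ("organelle_rdna", organelle_rdna_refs, screen_organelle_rdna),
    ):
        results = fn(remaining, refs, params)
        log.extend(results)
        removed_ids = {r.candidate_id for r in results if r.removed}
        remaining = [c for c in remaining if c.candidate_id not in removed_ids]
    return remaining, log


def screen_report_tsv(results: Sequence[ScreenResult]) -> str:
    lines = ["candidate\tscreen\tremoved\treason\thit"]
    for r in results:
        hit = ""
        if r.best_hit is not None:
            h = r.best_hit
            hit = f"{h.subject_id}:{h.s_start}-{h.s_end}"
        lines.append(f"{r.candidate_id}\t{r.screen}\t{int(r.removed)}\t{r.reason}\t{hit}")
    return "\n".join(lines) + "\n"
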