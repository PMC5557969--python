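"""End-to-end orchestration: reads -> profiles -> peaks -> packaging call."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import classify as cl
from . import coverage as cov
from . import seqmap as sm

logger = logging.getLogger(__name__)

SINGLE_END_CAVEAT = (
    "single-end input: sequence coverage approximates fragment coverage, so "
    "tau can reach 1 for cos phages whose fragments are longer than the "
    "reads and for phages with short terminal repeats; interpret tau-based "
    "subtypes with caution"
)


@dataclass
class AnalysisOptions:
    seed_length: int = 20
    merge_window: int = 20
    alpha: float = 0.01
    adjust: str = "bh"  # or "bonferroni"
    max_insert: int = 2000
    min_segment: int = 500
    max_depth: int = 4
    thresholds: cl.Thresholds = field(default_factory=cl.Thresholds)


@dataclass
class AnalysisResult:
    reference: sm.ReferenceGenome
    mapping: sm.MappingResult
    profiles: cov.StrandProfiles
    tau: cov.TauProfile
    segments: list[cov.GenomeSegment]
    peaks: cov.PeakResult
    call: cl.PackagingCall
    hybrid: cl.HybridEvidence | None = None
    transduction: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def paired(self) -> bool:
        return self.tau.paired


def _call_peak(result_peaks: cov.PeakResult, call: cl.PackagingCall, strand: str):
    """Locate the merged peak backing a terminus of the call."""
    pos = call.left_terminus if strand == "forward" else call.right_terminus
    if pos is None:
        return None
    for p in result_peaks.peaks(strand):
        if p.position == pos - 1:
            return p
    return None


def analyze(
    pairs,
    reference: sm.ReferenceGenome,
    host: sm.ReferenceGenome | None = None,
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full terminus/packaging analysis on in-memory reads.

    ``pairs`` is a sequence of ``(mate1, mate2 | None)`` read tuples as
    produced by :func:`phage_termini.seqmap.load_read_pairs` or the
    simulator.
    """
    opt = options or AnalysisOptions()
    opt.thresholds.validate()
    G = len(reference)
    paired = any(r2 is not None for _, r2 in pairs)

    mapping = sm.map_reads(
        pairs, reference, seed_length=opt.seed_length, max_insert=opt.max_insert
    )
    logger.info(
        "mapped %d/%d reads (%d multi-mapped, %d unmapped)",
        mapping.n_mapped, mapping.n_reads, mapping.n_multi, len(mapping.unmapped),
    )
    profiles = cov.build_profiles(mapping.alignments, mapping.fragments, G)
    use_fragments = paired and bool(mapping.fragments)
    tau = cov.compute_tau(
        profiles, paired=use_fragments, F=mapping.F,
        F_is_approximate=mapping.F_is_approximate,
    )
    segments = cov.segment_by_coverage(
        profiles, min_segment=opt.min_segment, max_depth=opt.max_depth
    )
    peaks = cov.call_peaks(
        tau, profiles, segments,
        alpha=opt.alpha, merge_window=opt.merge_window, adjust=opt.adjust,
    )

    call = cl.classify_from_peaks(
        peaks.peaks_fwd, peaks.peaks_rev, tau, profiles, G, opt.thresholds
    )

    hybrid = None
    transduction = None
    if host is not None:
        hybrid = cl.detect_hybrid_fragments(
            pairs, reference, host,
            seed_length=opt.seed_length, F=mapping.F,
            read_length=mapping.mean_read_length, paired=paired,
        )
        transduction = cl.transduction_metrics(hybrid, host)

    if call is None:
        if hybrid is not None:
            call = cl.classify_mu_or_headful(hybrid, G, opt.thresholds)
        else:
            call = cl.PackagingCall(
                phage_class="UNKNOWN",
                notes=[cl.T4_ADVISORY,
                       "no host genome provided: Mu-like analysis skipped"],
            )

    diagnostics = {
        "n_reads": mapping.n_reads,
        "n_mapped": mapping.n_mapped,
        "n_multi_mapped": mapping.n_multi,
        "n_unmapped": len(mapping.unmapped),
        "n_fragments": len(mapping.fragments),
        "mean_fragment_size": mapping.F,
        "fragment_size_approximate": mapping.F_is_approximate,
        "background_tau": tau.background_tau,
        "peak_size": [],
    }

    if call.phage_class in ("COS_5p", "COS_3p", "DTR_short", "DTR_long"):
        cl.extract_junction_sequence(call, reference)
    for strand in ("forward", "reverse"):
        peak = _call_peak(peaks, call, strand)
        if peak is None:
            continue
        ratio, flagged = cov.peak_size_diagnostic(peak, tau.R(strand), tau.F)
        diagnostics["peak_size"].append(
            {"strand": strand, "T_over_R": ratio, "flagged": flagged}
        )
        if flagged and call.phage_class not in ("HEADFUL_PAC",):
            call.notes.append(
                f"{strand} terminus signal T/R = {ratio:.0f} is well below the "
                f"mean fragment size ({tau.F:.0f}): inefficient end capture or "
                f"alternative termini"
            )
    if call.phage_class == "HEADFUL_PAC":
        strand = call.packaging_orientation or "forward"
        peak = _call_peak(peaks, call, strand)
        if peak is not None and 0 < peak.tau < 1:
            est = cl.estimate_concatemer_copies(
                tau=peak.tau, T=peak.SPC_merged, R=tau.R(strand), F=tau.F
            )
            call.concatemer_copies = est.mean
            diagnostics["concatemer_estimate"] = {
                "from_tau": est.from_tau, "from_peak_size": est.from_peak_size,
            }
    if not use_fragments:
        call.notes.append(SINGLE_END_CAVEAT)

    return AnalysisResult(
        reference=reference,
        mapping=mapping,
        profiles=profiles,
        tau=tau,
        segments=segments,
        peaks=peaks,
        call=call,
        hybrid=hybrid,
        transduction=transduction,
        diagnostics=diagnostics,
    )


@dataclass
class RunConfig:
    """File-level configuration of a pipeline run."""

    reads1: str
    reference: str
    reads2: str | None = None
    host: str | None = None
    single: bool = False
    outdir: str = "phage_termini_out"
    sample_name: str = "phage"
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    def validate(self) -> None:
        for path in filter(None, (self.reads1, self.reads2, self.reference, self.host)):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if self.options.alpha <= 0 or self.options.merge_window < 0:
            raise cl.ConfigError("alpha must be > 0 and merge window >= 0")


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Load files, analyze, and write the full set of report artifacts."""
    from . import report  # deferred: pulls in matplotlib

    config.validate()
    reference = sm.load_reference(config.reference)
    host = sm.load_reference(config.host) if config.host else None
    pairs = sm.load_read_pairs(
        config.reads1, None if config.single else config.reads2
    )
    result = analyze(pairs, reference, host=host, options=config.options)
    report.write_all(result, config.outdir, sample_name=config.sample_name)
    return result
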