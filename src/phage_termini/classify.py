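"""Packaging-mechanism classification from terminus peaks and hybrid reads.

Decision rules, applied in order:

1. *Multiple* — a strand carries more than one significant peak but none of
   its peaks exceeds tau = 0.35: the signal is ambiguous (e.g. a reference
   with the terminal repeat assembled at both ends).
2. Peaks with tau > 0.1 on *both* strands: the distance between the top
   peaks separates cohesive ends from terminal repeats.  The longest known
   cohesive overhang is 19 nt, the shortest known terminal repeat 131 bp,
   so the boundary sits at 20 bp.  Within 20 bp the call is *cos* — 5' if
   the forward peak lies left of the reverse peak, 3' otherwise.  At 20 bp
   or more, with inter-peak coverage at least 10% above the genome average,
   the call is a direct terminal repeat (short/long split at 1 kb).
3. A tau > 0.1 peak on exactly *one* strand: headful packaging from a pac
   site; the peak strand gives the packaging orientation and Eq. tau =
   1/(1+C) yields the concatemer size.
4. No peaks: headful-without-pac (T4-like) or a transposable (Mu-like)
   phage.  Mu-like phages carry host DNA at their termini, so read pairs
   with one mate on the phage and one on the host ("hybrid fragments")
   appear at a predictable rate 2*(F - 2S)/G; observing at least half that
   rate calls Mu-like, a positive-but-lower rate is annotated headful, and
   zero hybrids is reported unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import PeakCall, StrandProfiles, TauProfile
from .seqmap import ReadRecord, ReferenceGenome, SeedIndex, revcomp

logger = logging.getLogger(__name__)

PHAGE_CLASSES = (
    "COS_5p",
    "COS_3p",
    "DTR_short",
    "DTR_long",
    "HEADFUL_PAC",
    "HEADFUL",
    "MU_LIKE",
    "MULTIPLE",
    "UNKNOWN",
)

#: class exemplar names used in summary tables; heuristic labels only
CLASS_EXEMPLARS = {
    "COS_5p": "Lambda",
    "COS_3p": "HK97",
    "DTR_short": "T7",
    "DTR_long": "T5",
    "HEADFUL_PAC": "P1",
    "HEADFUL": "T4",
    "MU_LIKE": "Mu",
    "MULTIPLE": "",
    "UNKNOWN": "",
}

CONTAMINATION_NOTE = (
    "tau below 0.35 at both termini: the phage DNA may be contaminated "
    "with unpackaged (circular or prophage) DNA; deviating tau can also "
    "indicate a novel packaging mechanism"
)

T4_ADVISORY = (
    "no termini and no hybrid evidence: if the genome is known to be "
    "complete, a headful mechanism without a pac site (T4-like) is likely; "
    "protein-capped termini (phi29-like) would also leave no signal"
)

PURITY_CAVEAT = (
    "host-mapping read abundance reflects transduction frequency only if "
    "the phage capsids were purified in a way that excludes host DNA "
    "contamination"
)


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    """Classifier thresholds; defaults follow the published decision rules."""

    tau_min: float = 0.1  # minimum peak tau to count as a terminus signal
    tau_strong: float = 0.35  # below this, multi-peak strands are 'Multiple'
    cos_max_distance: int = 20  # bp separating cos from DTR calls
    dtr_coverage_gain: float = 1.1  # inter-peak coverage vs genome average
    dtr_long_min: int = 1000  # repeat length splitting DTR short/long
    mu_min_fraction: float = 0.5  # observed/expected hybrid ratio for Mu

    def validate(self) -> None:
        if not (0 < self.tau_min < self.tau_strong <= 1):
            raise ConfigError(
                f"need 0 < tau_min < tau_strong <= 1, got {self.tau_min}, "
                f"{self.tau_strong}"
            )
        if self.cos_max_distance < 1:
            raise ConfigError("cos_max_distance must be >= 1")
        if self.cos_max_distance >= self.dtr_long_min:
            raise ConfigError("cos_max_distance must be < dtr_long_min")
        if self.dtr_coverage_gain <= 1.0:
            raise ConfigError("dtr_coverage_gain must exceed 1.0")
        if not (0 < self.mu_min_fraction <= 1):
            raise ConfigError("mu_min_fraction must be in (0, 1]")


@dataclass
class PackagingCall:
    """The final classification and its derived quantities.

    Termini are 1-based inclusive; ``left_terminus`` is the forward-strand
    peak and ``right_terminus`` the reverse-strand peak (for 3' cohesive
    ends the 'left' coordinate therefore exceeds the 'right' one, matching
    the orientation of the underlying molecule ends).
    """

    phage_class: str
    left_terminus: int | None = None
    right_terminus: int | None = None
    termini_redundancy: str | None = None  # "redundant" | "non_redundant"
    junction_sequence: str | None = None
    packaging_orientation: str | None = None
    concatemer_copies: float | None = None
    tau_forward: float | None = None
    tau_reverse: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def exemplar(self) -> str:
        return CLASS_EXEMPLARS.get(self.phage_class, "")


def _top_peak(peaks: list[PeakCall]) -> PeakCall:
    # highest tau; ties broken by SPC_merged, then leftmost position
    return sorted(peaks, key=lambda p: (-p.tau, -p.SPC_merged, p.position))[0]


def classify_from_peaks(
    fwd_peaks: list[PeakCall],
    rev_peaks: list[PeakCall],
    tau_profile: TauProfile,
    profiles: StrandProfiles,
    G: int,
    thresholds: Thresholds | None = None,
) -> PackagingCall | None:
    """Apply the peak-based decision rules; return None to defer to the
    hybrid-fragment (Mu/headful) stage."""
    th = thresholds or Thresholds()
    th.validate()

    fp = [p for p in fwd_peaks if p.tau > th.tau_min]
    rp = [p for p in rev_peaks if p.tau > th.tau_min]

    # rule 1: Multiple
    for peaks in (fp, rp):
        if len(peaks) > 1 and all(p.tau <= th.tau_strong for p in peaks):
            return PackagingCall(
                phage_class="MULTIPLE",
                termini_redundancy="redundant",
                notes=[
                    "more than one significant peak on the same strand with "
                    "no peak above tau 0.35; check the assembly for "
                    "duplicated terminal repeats"
                ],
            )

    # rule 2: both strands.  Cos distances are evaluated circularly: when an
    # assembler opens the genome exactly at the cos site the two peaks sit at
    # opposite contig edges, but on the circle they are still adjacent.
    if fp and rp:
        pf, pr = _top_peak(fp), _top_peak(rp)
        d_fwd = (pr.position - pf.position) % G  # fwd terminus -> rev, rightwards
        d_rev = (pf.position - pr.position) % G
        call = None
        if min(d_fwd, d_rev) < th.cos_max_distance:
            call = PackagingCall(
                phage_class="COS_5p" if d_fwd < d_rev else "COS_3p",
                termini_redundancy="non_redundant",
            )
        else:
            denom = (
                profiles.FCOV
                if tau_profile.paired
                else profiles.COV_fwd + profiles.COV_rev
            )
            lo, hi = sorted((pf.position, pr.position))
            inter = denom[lo : hi + 1]
            rest = np.concatenate([denom[:lo], denom[hi + 1 :]])
            if (
                pf.position < pr.position
                and rest.size
                and inter.mean() >= th.dtr_coverage_gain * rest.mean()
            ):
                repeat_len = pr.position - pf.position + 1
                call = PackagingCall(
                    phage_class=(
                        "DTR_short" if repeat_len < th.dtr_long_min else "DTR_long"
                    ),
                    termini_redundancy="redundant",
                )
            else:
                logger.info(
                    "both-strand peaks at %d/%d do not fit cos or DTR "
                    "expectations; deferring",
                    pf.position,
                    pr.position,
                )
                return None
        call.left_terminus = pf.position + 1
        call.right_terminus = pr.position + 1
        call.tau_forward = pf.tau
        call.tau_reverse = pr.tau
        if pf.tau < th.tau_strong and pr.tau < th.tau_strong:
            call.notes.append(CONTAMINATION_NOTE)
        return call

    # rule 3: single strand => pac
    if fp or rp:
        peak = _top_peak(fp or rp)
        call = PackagingCall(
            phage_class="HEADFUL_PAC",
            termini_redundancy="redundant",
            packaging_orientation=peak.strand,
        )
        if peak.strand == "forward":
            call.left_terminus = peak.position + 1
            call.tau_forward = peak.tau
        else:
            call.right_terminus = peak.position + 1
            call.tau_reverse = peak.tau
        return call

    return None  # defer to the Mu/headful stage


@dataclass
class HybridEvidence:
    """Read pairs straddling a phage/host junction and related tallies."""

    hybrid_count: int
    total_phage_fragments: int
    observed_proportion: float
    expected_proportion: float
    host_positions: list[int] = field(default_factory=list)
    phage_side_positions: list[int] = field(default_factory=list)
    host_only_reads: int = 0
    total_reads: int = 0
    paired: bool = True


def _categorize(seq: str, phage_idx: SeedIndex, host_idx: SeedIndex):
    """('phage'|'host'|None, position|None).  Phage has priority: a read
    mapping uniquely to the phage is called phage even if it also matches
    the host (relevant when the host carries the prophage)."""
    S = phage_idx.k
    if len(seq) < S:
        return None, None
    seed, rc = seq[:S], revcomp(seq[:S])
    fwd, rev = phage_idx.hits(seed), phage_idx.hits(rc)
    if len(fwd) + len(rev) == 1:
        return "phage", fwd[0] if fwd else rev[0] + S - 1
    if len(fwd) + len(rev) > 1:
        return None, None
    fwd, rev = host_idx.hits(seed), host_idx.hits(rc)
    if len(fwd) + len(rev) == 1:
        return "host", fwd[0] if fwd else rev[0] + S - 1
    return None, None


def detect_hybrid_fragments(
    pairs: list[tuple[ReadRecord, ReadRecord | None]],
    phage_ref: ReferenceGenome,
    host_ref: ReferenceGenome | None,
    seed_length: int,
    F: float,
    read_length: float | None = None,
    paired: bool = True,
) -> HybridEvidence:
    """Count fragments with one side on the phage and one on the host.

    Paired data: a pair with exactly one mate seed-mapping to the phage and
    the other to the host.  Single-end data: a read whose first S bases map
    to one genome and whose last S bases map to the other.  The closed-form
    expectation for a Mu-like phage is 2*(F - 2S)/G (F replaced by the read
    length for single-end data): out of ~G/F phage fragments per particle,
    two straddle a junction, and a straddling fragment is only detectable
    when both sides are at least as long as the seed S.
    """
    if host_ref is None:
        raise ValueError("host genome required for hybrid-fragment analysis")
    S = seed_length
    G = len(phage_ref)
    phage_idx = SeedIndex(phage_ref.sequence, S)
    host_idx = SeedIndex(host_ref.sequence, S)

    hybrid = 0
    phage_frags = 0
    host_only_reads = 0
    total_reads = 0
    host_positions: list[int] = []
    phage_positions: list[int] = []

    for r1, r2 in pairs:
        if paired and r2 is not None:
            cats = [_categorize(r.sequence, phage_idx, host_idx) for r in (r1, r2)]
            total_reads += 2
            labels = [c[0] for c in cats]
            host_only_reads += labels.count("host") if "phage" not in labels else 0
            if "phage" in labels:
                phage_frags += 1
            if sorted(x for x in labels if x) == ["host", "phage"]:
                hybrid += 1
                for label, pos in cats:
                    if label == "host":
                        host_positions.append(pos)
                    elif label == "phage":
                        phage_positions.append(pos)
        else:
            total_reads += 1
            seq = r1.sequence
            head, hp = _categorize(seq, phage_idx, host_idx)
            tail, tp = (
                _categorize(seq[-S:], phage_idx, host_idx)
                if len(seq) >= 2 * S
                else (None, None)
            )
            if head == "phage" or tail == "phage":
                phage_frags += 1
            elif head == "host" or tail == "host":
                host_only_reads += 1
            if head and tail and head != tail:
                hybrid += 1
                for label, pos in ((head, hp), (tail, tp)):
                    if label == "host":
                        host_positions.append(pos)
                    else:
                        phage_positions.append(pos)

    F_eff = F if paired else float(read_length or F)
    expected = 2.0 * (F_eff - 2.0 * S) / G
    observed = hybrid / phage_frags if phage_frags else 0.0
    return HybridEvidence(
        hybrid_count=hybrid,
        total_phage_fragments=phage_frags,
        observed_proportion=observed,
        expected_proportion=expected,
        host_positions=host_positions,
        phage_side_positions=phage_positions,
        host_only_reads=host_only_reads,
        total_reads=total_reads,
        paired=paired,
    )


def classify_mu_or_headful(
    evidence: HybridEvidence,
    G: int,
    thresholds: Thresholds | None = None,
) -> PackagingCall:
    """Decide Mu-like vs headful vs unknown when no terminus peaks exist."""
    th = thresholds or Thresholds()
    if evidence.expected_proportion <= 0:
        raise ValueError(
            "hybrid expectation is non-positive (needs F > 2*S); cannot "
            "assess the Mu-like class"
        )
    if evidence.observed_proportion >= th.mu_min_fraction * evidence.expected_proportion:
        call = PackagingCall(
            phage_class="MU_LIKE",
            termini_redundancy="non_redundant",
            notes=[
                f"hybrid fragments observed at "
                f"{100 * evidence.observed_proportion:.2f}% vs expected "
                f"{100 * evidence.expected_proportion:.2f}%"
            ],
        )
        if evidence.phage_side_positions:
            pos = np.asarray(evidence.phage_side_positions)
            call.left_terminus = int(np.percentile(pos, 2.5)) + 1
            call.right_terminus = int(np.percentile(pos, 97.5)) + 1
            call.notes.append(
                "termini estimated from phage-side positions of hybrid "
                "fragments (2.5th/97.5th percentiles); short-read data "
                "cannot size the host flanks"
            )
        return call
    if evidence.hybrid_count > 0:
        return PackagingCall(
            phage_class="HEADFUL",
            termini_redundancy="redundant",
            notes=[
                f"hybrid fragments present ({100 * evidence.observed_proportion:.2f}%) "
                f"but below half the Mu-like expectation "
                f"({100 * evidence.expected_proportion:.2f}%)"
            ],
        )
    return PackagingCall(phage_class="UNKNOWN", notes=[T4_ADVISORY])


@dataclass
class ConcatemerEstimate:
    from_tau: float | None
    from_peak_size: float | None

    @property
    def mean(self) -> float | None:
        vals = [v for v in (self.from_tau, self.from_peak_size) if v is not None]
        return sum(vals) / len(vals) if vals else None


def estimate_concatemer_copies(
    tau: float | None = None,
    T: float | None = None,
    R: float | None = None,
    F: float | None = None,
) -> ConcatemerEstimate:
    """Concatemer size C = 1/tau - 1 = F*R/T - 1 for a pac phage.

    Both forms are returned when computable; negative estimates (signal
    stronger than a fixed terminus would give) are clipped to None with a
    warning.
    """
    c_tau = c_tr = None
    if tau is not None:
        if tau >= 1:
            raise ValueError(f"tau = {tau} >= 1 is not compatible with pac packaging")
        if tau > 0:
            c_tau = 1.0 / tau - 1.0
    if T is not None and R is not None and F is not None and T > 0:
        c_tr = F * R / T - 1.0
    est = ConcatemerEstimate(from_tau=c_tau, from_peak_size=c_tr)
    for name in ("from_tau", "from_peak_size"):
        v = getattr(est, name)
        if v is not None and v < 0:
            logger.warning("concatemer estimate %s is negative (%.3f); dropped", name, v)
            setattr(est, name, None)
    return est


def extract_junction_sequence(
    call: PackagingCall, ref: ReferenceGenome
) -> PackagingCall:
    """Attach the cos overhang / DTR repeat sequence between the termini.

    Reported as the closed 1-based interval spanning the two peak positions.
    For 5' cohesive ends this is exactly the shared overhang; for 3' ends it
    brackets the overhang resected during end repair (the sequence is taken
    from the reference, since no read retains it); for terminal repeats it
    is the repeat, reported once.
    """
    if call.phage_class not in ("COS_5p", "COS_3p", "DTR_short", "DTR_long"):
        raise ValueError(f"no junction sequence for class {call.phage_class}")
    if call.left_terminus is None or call.right_terminus is None:
        raise ValueError("both termini required to extract the junction")
    lo, hi = sorted((call.left_terminus, call.right_terminus))
    if lo < 1 or hi > len(ref):
        raise ValueError(f"termini {lo}..{hi} outside the genome (1..{len(ref)})")
    if call.phage_class.startswith("COS") and hi - lo + 1 > len(ref) // 2:
        # termini at opposite contig edges: the junction wraps the origin
        call.junction_sequence = ref.sequence[hi - 1 :] + ref.sequence[:lo]
    else:
        call.junction_sequence = ref.sequence[lo - 1 : hi]
    return call


def transduction_metrics(
    evidence: HybridEvidence,
    host_ref: ReferenceGenome,
    bin_size: int = 500,
) -> dict:
    """Host-only read fraction and a putative attachment-site scan.

    The host-only fraction is a generalized-transduction proxy.  The
    host-side positions of hybrid fragments are binned; a dominant bin marks
    a putative attachment site (specialized transduction or prophage
    contamination, undifferentiated).
    """
    frac = (
        evidence.host_only_reads / evidence.total_reads
        if evidence.total_reads
        else 0.0
    )
    n_bins = max(1, len(host_ref) // bin_size)
    counts, edges = np.histogram(
        evidence.host_positions, bins=n_bins, range=(0, len(host_ref))
    )
    site = None
    uniform_mean = counts.sum() / n_bins  # expectation without any hotspot
    if counts.sum() and counts.max() >= 10 and counts.max() > 5 * uniform_mean:
        b = int(np.argmax(counts))
        site = int((edges[b] + edges[b + 1]) / 2) + 1  # 1-based bin centre
    return {
        "host_read_fraction": frac,
        "attachment_site": site,
        "histogram": (edges, counts),
        "caveat": PURITY_CAVEAT,
    }
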