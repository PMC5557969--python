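"""Structured outputs and the human-readable report.

Everything here is pure presentation of an :class:`AnalysisResult`: a
per-position statistics table (CSV), the peak table (CSV), the packaging
call (CSV row + JSON), the junction sequence and reorganized genome
(FASTA), per-strand SPC/tau plots (PNG) and a text + HTML report.  All
user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import html
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

COORD_NOTE = "# coordinates are 1-based inclusive"


def stats_table(result) -> pd.DataFrame:
    G = result.profiles.G
    return pd.DataFrame(
        {
            "position": np.arange(1, G + 1),
            "SPC_fwd": result.profiles.SPC_fwd,
            "SPC_rev": result.profiles.SPC_rev,
            "COV_fwd": result.profiles.COV_fwd,
            "COV_rev": result.profiles.COV_rev,
            "FCOV": result.profiles.FCOV,
            "tau_fwd": result.tau.tau_fwd,
            "tau_rev": result.tau.tau_rev,
            "pvalue_fwd": result.peaks.pvalues["forward"],
            "pvalue_rev": result.peaks.pvalues["reverse"],
            "adjusted_pvalue_fwd": result.peaks.adjusted_pvalues["forward"],
            "adjusted_pvalue_rev": result.peaks.adjusted_pvalues["reverse"],
        }
    )


def peaks_table(result) -> pd.DataFrame:
    rows = [
        {
            "strand": p.strand,
            "position": p.position + 1,
            "tau": p.tau,
            "SPC_merged": p.SPC_merged,
            "pvalue": p.pvalue,
            "adjusted_pvalue": p.adjusted_pvalue,
            "merged_positions": ";".join(str(m + 1) for m in p.members),
        }
        for p in result.peaks.all_peaks
    ]
    return pd.DataFrame(
        rows,
        columns=["strand", "position", "tau", "SPC_merged", "pvalue",
                 "adjusted_pvalue", "merged_positions"],
    )


_ENDS = {"redundant": "Redundant", "non_redundant": "Non Redundant"}

_CLASS_LABEL = {
    "COS_5p": "COS (5')",
    "COS_3p": "COS (3')",
    "DTR_short": "DTR (short)",
    "DTR_long": "DTR (long)",
    "HEADFUL_PAC": "Headful (pac)",
    "HEADFUL": "Headful",
    "MU_LIKE": "Mu-like",
    "MULTIPLE": "Multiple",
    "UNKNOWN": "-",
}


def call_row(result, sample_name: str = "phage") -> dict:
    call = result.call
    left = call.left_terminus
    right = call.right_terminus
    if call.phage_class == "HEADFUL_PAC":
        left = left if left is not None else "Distributed"
        right = right if right is not None else "Distributed"
    elif call.phage_class in ("HEADFUL",):
        left = right = "Random"
    elif left is None:
        left = right = "-"
    return {
        "Phage": sample_name,
        "Ends": _ENDS.get(call.termini_redundancy, "-"),
        "Left": left,
        "Right": right,
        "Class": _CLASS_LABEL.get(call.phage_class, call.phage_class),
        "Type": call.exemplar or "-",
    }


def call_json(result, sample_name: str = "phage") -> dict:
    call = result.call
    return {
        "sample": sample_name,
        "class": call.phage_class,
        "left_terminus": call.left_terminus,
        "right_terminus": call.right_terminus,
        "termini_redundancy": call.termini_redundancy,
        "junction_sequence": call.junction_sequence,
        "packaging_orientation": call.packaging_orientation,
        "concatemer_copies": call.concatemer_copies,
        "tau_forward": call.tau_forward,
        "tau_reverse": call.tau_reverse,
        "notes": call.notes,
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if k != "peak_size"
        },
        "peak_size": result.diagnostics.get("peak_size", []),
        "hybrid": None
        if result.hybrid is None
        else {
            "hybrid_count": result.hybrid.hybrid_count,
            "total_phage_fragments": result.hybrid.total_phage_fragments,
            "observed_proportion": result.hybrid.observed_proportion,
            "expected_proportion": result.hybrid.expected_proportion,
        },
        "transduction": None
        if result.transduction is None
        else {
            "host_read_fraction": result.transduction["host_read_fraction"],
            "attachment_site": result.transduction["attachment_site"],
            "caveat": result.transduction["caveat"],
        },
    }


def reorganized_genome(result) -> tuple[str, str]:
    """Genome sequence reorganized to start at the identified terminus.

    Fixed-end classes are rotated to begin at the forward terminus; a
    terminal repeat is appended once at the right end; pac genomes are
    rotated to begin at the packaging site.  Classes without fixed termini
    are returned unchanged.
    """
    call = result.call
    seq = result.reference.sequence
    if call.phage_class in ("COS_5p", "COS_3p", "DTR_short", "DTR_long"):
        start = call.left_terminus - 1
        rotated = seq[start:] + seq[:start]
        if call.phage_class.startswith("DTR"):
            repeat = len(call.junction_sequence or "")
            rotated += rotated[:repeat]
            return rotated, "rotated to the left terminus; terminal repeat appended"
        return rotated, "rotated to the left terminus"
    if call.phage_class == "HEADFUL_PAC":
        pos = call.left_terminus or call.right_terminus
        if pos:
            start = pos - 1
            return seq[start:] + seq[:start], "rotated to the pac site"
    return seq, "unchanged (no fixed termini)"


def text_report(result, sample_name: str = "phage") -> str:
    call = result.call
    d = result.diagnostics
    lines = [
        f"Packaging analysis report: {sample_name}",
        "=" * 60,
        f"Genome length        : {result.profiles.G}",
        f"Reads (mapped/total) : {d['n_mapped']}/{d['n_reads']} "
        f"(multi {d['n_multi_mapped']}, unmapped {d['n_unmapped']})",
        f"Fragments            : {d['n_fragments']}",
        f"Mean fragment size F : {d['mean_fragment_size']:.1f}"
        + (" (approximate, single-end)" if d["fragment_size_approximate"] else ""),
        f"Background tau (1/F) : {d['background_tau']:.5f}",
        "",
        f"Class                : {_CLASS_LABEL.get(call.phage_class)} "
        f"[{call.phage_class}]",
        f"Ends                 : {_ENDS.get(call.termini_redundancy, '-')}",
        f"Left terminus        : {call.left_terminus or '-'}"
        + (f"  (tau {call.tau_forward:.3f})" if call.tau_forward else ""),
        f"Right terminus       : {call.right_terminus or '-'}"
        + (f"  (tau {call.tau_reverse:.3f})" if call.tau_reverse else ""),
    ]
    if call.packaging_orientation:
        lines.append(f"Packaging orientation: {call.packaging_orientation}")
    if call.concatemer_copies is not None:
        lines.append(f"Concatemer copies C  : {call.concatemer_copies:.1f}")
    if call.junction_sequence:
        lines.append(
            f"Junction ({len(call.junction_sequence)} nt)    : "
            f"{call.junction_sequence}"
        )
    for entry in d.get("peak_size", []):
        flag = "  ** below F/2: inefficient end capture or alternative termini"
        lines.append(
            f"T/R ({entry['strand']:7s})        : {entry['T_over_R']:.0f}"
            + (flag if entry["flagged"] else "")
        )
    if result.hybrid is not None:
        h = result.hybrid
        lines += [
            "",
            "Hybrid-fragment (Mu-like) analysis:",
            f"  hybrid fragments   : {h.hybrid_count} / {h.total_phage_fragments}",
            f"  observed proportion: {100 * h.observed_proportion:.2f}%",
            f"  expected 2(F-2S)/G : {100 * h.expected_proportion:.2f}%",
        ]
    if result.transduction is not None:
        t = result.transduction
        lines += [
            "",
            "Transduction analysis:",
            f"  host-only read fraction: {100 * t['host_read_fraction']:.2f}%",
            f"  putative attachment site: {t['attachment_site'] or 'none detected'}",
            f"  note: {t['caveat']}",
        ]
    if call.notes:
        lines += ["", "Notes:"] + [f"  - {n}" for n in call.notes]
    return "\n".join(lines) + "\n"


def plot_profiles(result, path, window: int = 1500) -> None:
    """SPC and tau per strand, zoomed around the called termini (or
    genome-wide when no termini were found)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = result.profiles.G
    call = result.call
    centers = [t - 1 for t in (call.left_terminus, call.right_terminus) if t]
    fig, axes = plt.subplots(2, 2, figsize=(11, 6), sharex="col")
    if centers:
        lo = max(0, min(centers) - window)
        hi = min(G, max(centers) + window)
    else:
        lo, hi = 0, G
    x = np.arange(lo, hi) + 1
    for col, (name, spc, tau) in enumerate(
        [
            ("forward", result.profiles.SPC_fwd, result.tau.tau_fwd),
            ("reverse", result.profiles.SPC_rev, result.tau.tau_rev),
        ]
    ):
        axes[0, col].plot(x, spc[lo:hi], lw=0.7, color="C0")
        axes[0, col].set_title(f"{name} strand")
        axes[0, col].set_ylabel("SPC")
        axes[1, col].plot(x, tau[lo:hi], lw=0.7, color="C1")
        axes[1, col].set_ylabel("tau")
        axes[1, col].set_xlabel("genome position (1-based)")
        for c in centers:
            for row in (0, 1):
                axes[row, col].axvline(c + 1, color="red", ls=":", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def html_report(result, sample_name: str, plot_file: str | None) -> str:
    body = html.escape(text_report(result, sample_name))
    img = f'<img src="{plot_file}" alt="SPC and tau profiles">' if plot_file else ""
    return (
        "<!doctype html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(sample_name)} packaging report</title></head>"
        f"<body><pre>{body}</pre>{img}</body></html>\n"
    )


def write_all(result, outdir, sample_name: str = "phage") -> dict:
    """Write every artifact; returns a dict of paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["stats"] = out / f"{sample_name}_statistics.csv"
    with open(paths["stats"], "w") as fh:
        fh.write(COORD_NOTE + "\n")
        stats_table(result).to_csv(fh, index=False)

    paths["peaks"] = out / f"{sample_name}_peaks.csv"
    with open(paths["peaks"], "w") as fh:
        fh.write(COORD_NOTE + "\n")
        peaks_table(result).to_csv(fh, index=False)

    paths["call_csv"] = out / f"{sample_name}_call.csv"
    pd.DataFrame([call_row(result, sample_name)]).to_csv(paths["call_csv"], index=False)

    paths["call_json"] = out / f"{sample_name}_call.json"
    with open(paths["call_json"], "w") as fh:
        json.dump(call_json(result, sample_name), fh, indent=2, default=float)

    if result.call.junction_sequence:
        paths["junction"] = out / f"{sample_name}_junction.fasta"
        SeqIO.write(
            [SeqRecord(Seq(result.call.junction_sequence),
                       id=f"{sample_name}_junction",
                       description=f"{result.call.phage_class} junction")],
            str(paths["junction"]), "fasta",
        )

    seq, desc = reorganized_genome(result)
    paths["reorganized"] = out / f"{sample_name}_reorganized.fasta"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=f"{sample_name}_reorganized", description=desc)],
        str(paths["reorganized"]), "fasta",
    )

    plot_file = None
    try:
        paths["plot"] = out / f"{sample_name}_profiles.png"
        plot_profiles(result, paths["plot"])
        plot_file = paths["plot"].name
    except Exception as exc:  # plotting must never abort an analysis
        logger.warning("profile plot failed: %s", exc)

    paths["report_txt"] = out / f"{sample_name}_report.txt"
    paths["report_txt"].write_text(text_report(result, sample_name))
    paths["report_html"] = out / f"{sample_name}_report.html"
    paths["report_html"].write_text(html_report(result, sample_name, plot_file))
    return paths
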