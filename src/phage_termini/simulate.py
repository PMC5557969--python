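"""Packaging-aware read simulator with per-read ground truth.

The generator emulates the physics that creates the terminus signal: a
natural DNA end occurs once per packaged molecule, while ends produced by
random fragmentation fall anywhere.  Each packaging class dictates the
shape of the packaged linear molecules:

``cos5``
    Fixed termini with a short 5' cohesive overhang.  End repair fills 5'
    overhangs, so both terminal fragments carry the overhang sequence: the
    repaired molecule is the genome plus one extra copy of the overhang at
    its right end, and tau at each terminus is ~0.5.
``cos3``
    Fixed termini with a 3' overhang, which end repair resects: the
    overhang is absent from every read, the inter-termini gap has zero
    coverage and tau at each terminus is ~1.
``dtr``
    A direct terminal repeat present at both molecule ends while the
    reference (assembler convention) carries it once; tau ~0.5 at both
    termini and doubled coverage over the repeat.
``pac``
    Headful packaging from a concatemer of C genome copies, first cut at a
    pac site, then every headful (one genome plus a small random overshoot);
    1/C of molecules start at the pac site and tau there is ~1/(1+C).
``headful``
    As ``pac`` but with the first cut at a random position: circularly
    permuted molecules, no terminus signal at all.
``mu``
    Transposition-amplified phage: each molecule is the phage genome flanked
    by host DNA (one short ~50 bp flank, one long ~2 kb flank), detectable
    only through hybrid phage/host read pairs.

Because contaminating circular DNA blurs where an assembler opens a cos/DTR
contig, fixed-termini references are emitted rotated so the termini sit at
an internal position (configurable, default G/4) rather than at the contig
edges.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqmap import ReadRecord, ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

SIM_CLASSES = ("cos5", "cos3", "dtr", "pac", "headful", "mu")

#: packaging call expected from the pipeline for each simulated class
#: (headful without host information yields UNKNOWN: no peaks, no hybrids)
EXPECTED_CALL = {
    "cos5": "COS_5p",
    "cos3": "COS_3p",
    "dtr": "DTR_short",
    "pac": "HEADFUL_PAC",
    "headful": "UNKNOWN",
    "mu": "MU_LIKE",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimScenario:
    """Parameters of a synthetic sequencing library.

    ``n_fragments`` is the approximate total fragment budget; the particle
    count is derived from it unless ``n_particles`` is given explicitly.
    Defaults reproduce a typical randomly fragmented Illumina library:
    400 +/- 60 bp fragments, 100 bp paired reads, ~100x fragment coverage
    of a 40 kb genome from 10^4 fragments.
    """

    phage_class: str = "cos3"
    genome_length: int = 40_000
    dtr_length: int = 160
    cos_overhang: int = 12
    concatemer_copies: int = 4
    pac_sites: list[tuple[int, float]] | None = None  # (position, weight)
    headful_overshoot: tuple[float, float] = (0.02, 0.10)  # fraction of G
    host_length: int = 150_000
    n_particles: int | None = None
    n_fragments: int = 10_000
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    read_length: int = 100
    paired: bool = True
    end_repair: str = "fill_5p_cut_3p"  # or "none"
    contamination_circular_fraction: float = 0.0
    host_only_read_fraction: float = 0.0
    mu_flank_short: tuple[int, int] = (40, 60)
    mu_flank_long: tuple[int, int] = (1500, 2500)
    prophage: bool = False
    duplicated_repeat: bool = False
    #: emulate transposase (Nextera-like) libraries, which never capture the
    #: molecule ends: terminal fragments are discarded
    discard_terminal_fragments: bool = False
    terminus_position: int | None = None  # default G // 4
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.phage_class not in SIM_CLASSES:
            raise ValueError(f"unknown packaging class {self.phage_class!r}")
        if self.phage_class == "pac" and self.concatemer_copies < 2:
            raise ValueError("pac packaging requires concatemer_copies >= 2")
        if self.dtr_length >= self.genome_length:
            raise ValueError("dtr_length must be smaller than the genome")
        for frac in (self.contamination_circular_fraction, self.host_only_read_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be within [0, 1]")

    @property
    def terminus(self) -> int:
        return (
            self.terminus_position
            if self.terminus_position is not None
            else self.genome_length // 4
        )

    @property
    def needs_host(self) -> bool:
        return self.phage_class == "mu" or self.host_only_read_fraction > 0


@dataclass(slots=True)
class TruthRead:
    read_id: str
    mate: int
    ref: str  # "phage" | "host" | "junction"
    strand: str
    start: int  # 0-based per the mapper's conventions; -1 for junction reads


class Molecule:
    """A packaged linear DNA molecule as blocks of reference intervals.

    Blocks are ``(ref_name, start, end)`` half-open top-strand intervals;
    adjacent contiguous blocks are coalesced so that reads crossing a
    seamless junction still get a well-defined true position.
    """

    __slots__ = ("blocks", "length")

    def __init__(self, blocks):
        merged = []
        for name, s, e in blocks:
            if e <= s:
                continue
            if merged and merged[-1][0] == name and merged[-1][2] == s:
                merged[-1] = (name, merged[-1][1], e)
            else:
                merged.append((name, s, e))
        self.blocks = merged
        self.length = sum(e - s for _, s, e in merged)

    def sequence(self, refs: dict[str, str]) -> str:
        return "".join(refs[name][s:e] for name, s, e in self.blocks)

    def locate(self, offset: int, length: int):
        """(ref_name, genome_start) of a span, or None if it crosses blocks."""
        for name, s, e in self.blocks:
            size = e - s
            if offset < size:
                if offset + length <= size:
                    return name, s + offset
                return None
            offset -= size
        return None


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _circ_blocks(name: str, start: int, length: int, G: int):
    """Blocks tracing ``length`` bases around a circular reference from
    ``start``; may wrap multiple times (concatemers)."""
    blocks = []
    pos = start % G
    while length > 0:
        take = min(G - pos, length)
        blocks.append((name, pos, pos + take))
        length -= take
        pos = (pos + take) % G
    return blocks


def make_genomes(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[ReferenceGenome, ReferenceGenome | None, dict]:
    """Random phage (and optional host) genomes.

    Returns ``(phage_reference, host_reference, info)`` where the phage
    reference follows the assembler convention for the class (repeat once;
    or twice for the ``duplicated_repeat`` failure-mode variant) and
    ``info`` records the prophage insertion site when one is embedded.
    """
    G = scenario.genome_length
    genome = _random_sequence(rng, G)
    info: dict = {}

    if scenario.phage_class == "dtr" and scenario.duplicated_repeat:
        t = scenario.terminus
        rotated = genome[t:] + genome[:t]
        ref_seq = rotated + rotated[: scenario.dtr_length]
    else:
        ref_seq = genome
    phage = ReferenceGenome(id="phage", sequence=ref_seq)

    host = None
    if scenario.needs_host:
        core = _random_sequence(rng, scenario.host_length)
        if scenario.prophage:
            q = scenario.host_length // 2
            host = ReferenceGenome(id="host", sequence=core[:q] + genome + core[q:])
            info["prophage_site"] = q
        else:
            host = ReferenceGenome(id="host", sequence=core)
    return phage, host, info


def _derive_particles(scenario: SimScenario, molecule_length: float) -> int:
    if scenario.n_particles is not None:
        return scenario.n_particles
    frags_per_molecule = max(1.0, molecule_length / scenario.fragment_mean)
    return max(1, round(scenario.n_fragments / frags_per_molecule))


def package_particles(
    scenario: SimScenario,
    genome: ReferenceGenome,
    host: ReferenceGenome | None,
    rng: np.random.Generator,
) -> list[Molecule]:
    """Generate the packaged linear molecules for the scenario."""
    G = scenario.genome_length
    t = scenario.terminus
    cls = scenario.phage_class
    repair = scenario.end_repair == "fill_5p_cut_3p"
    molecules: list[Molecule] = []

    if cls in ("cos5", "cos3", "dtr"):
        if cls == "dtr":
            start, length = t, G + scenario.dtr_length
        elif cls == "cos5":
            extra = scenario.cos_overhang if repair else 0
            start, length = t, G + extra
        else:  # cos3: resected overhang leaves a gap of cos_overhang bases
            gap = scenario.cos_overhang if repair else 0
            start, length = t + gap, G - gap
        n = _derive_particles(scenario, length)
        blocks = _circ_blocks("phage", start, length, G)
        molecules = [Molecule(blocks) for _ in range(n)]

    elif cls in ("pac", "headful"):
        C = scenario.concatemer_copies
        mean_len = G * (1 + np.mean(scenario.headful_overshoot))
        n = _derive_particles(scenario, mean_len)
        n_concat = max(1, round(n / C))
        sites = scenario.pac_sites or [(t, 1.0)]
        positions = np.array([p for p, _ in sites])
        weights = np.array([w for _, w in sites], dtype=float)
        weights /= weights.sum()
        lo, hi = scenario.headful_overshoot
        for _ in range(n_concat):
            if cls == "pac":
                start = int(rng.choice(positions, p=weights))
            else:
                start = int(rng.integers(G))
            pos = 0
            # processive series of C headfuls from one concatemer
            for _ in range(C):
                h = int(round(G * (1 + rng.uniform(lo, hi))))
                molecules.append(
                    Molecule(_circ_blocks("phage", start + pos, h, G))
                )
                pos += h

    elif cls == "mu":
        if host is None:
            raise ValueError("mu scenario requires a host genome")
        H = len(host)
        n = _derive_particles(
            scenario,
            G + np.mean(scenario.mu_flank_short) + np.mean(scenario.mu_flank_long),
        )
        q = scenario.host_length // 2 if scenario.prophage else None
        for _ in range(n):
            l1 = int(rng.integers(*scenario.mu_flank_short, endpoint=True))
            l2 = int(rng.integers(*scenario.mu_flank_long, endpoint=True))
            if q is not None:
                a, b = q - l1, q + G  # flanks adjacent to the prophage
            else:
                a = int(rng.integers(0, H - l1))
                b = int(rng.integers(0, H - l2))
            molecules.append(
                Molecule(
                    [("host", a, a + l1), ("phage", 0, G), ("host", b, b + l2)]
                )
            )
    return molecules


def _partition_molecule(
    length: int, scenario: SimScenario, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Cut one molecule into fragments with ~Normal(F, sd) sizes.

    Sizes are drawn until they overshoot the molecule and then rescaled so
    the partition is exact; this keeps both terminal fragments ordinary
    draws instead of leaving a runt at the right end.
    """
    rl = scenario.read_length
    if length < rl:
        return []
    F, sd = scenario.fragment_mean, scenario.fragment_sd
    if length <= F + 2 * sd:
        return [(0, length)]
    sizes: list[float] = []
    total = 0.0
    while total < length:
        s = max(float(rl), rng.normal(F, sd))
        sizes.append(s)
        total += s
    bounds = np.rint(np.cumsum(sizes) * (length / total)).astype(int)
    bounds[-1] = length
    edges = np.concatenate([[0], bounds])
    frags = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a >= rl:
            frags.append((int(a), int(b - a)))
        else:
            logger.debug("dropping %d bp runt fragment", b - a)
    return frags


def fragment_and_repair(
    molecules: list[Molecule], scenario: SimScenario, rng: np.random.Generator
) -> list[tuple[Molecule, int, int]]:
    """Random fragmentation of every molecule: ``(molecule, offset, size)``.

    End-repair chemistry is already encoded in the molecule construction
    (filled 5' overhangs appear as an extra terminal copy of the overhang;
    resected 3' overhangs as a coverage gap), so terminal fragments simply
    inherit the molecule ends.
    """
    out = []
    for mol in molecules:
        frags = _partition_molecule(mol.length, scenario, rng)
        if scenario.discard_terminal_fragments:
            frags = [
                (off, size)
                for off, size in frags
                if off > 0 and off + size < mol.length
            ]
        for off, size in frags:
            out.append((mol, off, size))
    return out


def _contamination_fragments(
    scenario: SimScenario,
    n_frags: int,
    host: ReferenceGenome | None,
    rng: np.random.Generator,
) -> list[tuple[Molecule, int, int]]:
    """Circular-phage contamination and host-only spike-in fragments."""
    extra = []
    G = scenario.genome_length
    rl = scenario.read_length
    n_circ = round(scenario.contamination_circular_fraction * n_frags)
    for _ in range(n_circ):
        size = max(rl, int(rng.normal(scenario.fragment_mean, scenario.fragment_sd)))
        start = int(rng.integers(G))
        extra.append((Molecule(_circ_blocks("phage", start, size, G)), 0, size))
    n_host = round(scenario.host_only_read_fraction * n_frags)
    if n_host and host is None:
        raise ValueError("host_only_read_fraction > 0 requires a host genome")
    for _ in range(n_host):
        size = max(rl, int(rng.normal(scenario.fragment_mean, scenario.fragment_sd)))
        start = int(rng.integers(len(host) - size))
        extra.append((Molecule([("host", start, start + size)]), 0, size))
    return extra


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        arr[hits] = rng.choice(_BASES, size=hits.size)
    return arr.tobytes().decode()


def build_reads(
    fragments: list[tuple[Molecule, int, int]],
    scenario: SimScenario,
    refs: dict[str, str],
    rng: np.random.Generator,
) -> tuple[list[tuple[ReadRecord, ReadRecord | None]], list[TruthRead]]:
    """Sequence each fragment into reads plus a per-read truth log."""
    rl = scenario.read_length
    pairs = []
    truth = []
    seq_cache: dict[int, str] = {}
    for i, (mol, off, size) in enumerate(fragments):
        mseq = seq_cache.get(id(mol))
        if mseq is None:
            mseq = mol.sequence(refs)
            seq_cache[id(mol)] = mseq
        frag = mseq[off : off + size]
        rid = f"sim_{i}"
        if not scenario.paired and rng.random() < 0.5:
            # single-end libraries read each fragment from a random end
            r1 = ReadRecord(
                rid, _mutate(revcomp(frag[-rl:]), scenario.substitution_rate, rng)
            )
            loc = mol.locate(off + size - rl, rl)
            truth.append(
                TruthRead(rid, 0, loc[0] if loc else "junction", "reverse",
                          loc[1] + rl - 1 if loc else -1)
            )
            pairs.append((r1, None))
            continue
        r1 = ReadRecord(rid, _mutate(frag[:rl], scenario.substitution_rate, rng),
                        mate=1 if scenario.paired else 0)
        loc = mol.locate(off, rl)
        truth.append(
            TruthRead(rid, r1.mate, loc[0] if loc else "junction", "forward",
                      loc[1] if loc else -1)
        )
        r2 = None
        if scenario.paired:
            tail = frag[-rl:]
            r2 = ReadRecord(rid, _mutate(revcomp(tail), scenario.substitution_rate, rng),
                            mate=2)
            loc2 = mol.locate(off + size - rl, rl)
            truth.append(
                TruthRead(rid, 2, loc2[0] if loc2 else "junction", "reverse",
                          loc2[1] + rl - 1 if loc2 else -1)
            )
        pairs.append((r1, r2))
    return pairs, truth


def _true_termini(scenario: SimScenario) -> dict:
    """1-based termini the pipeline should recover, per class."""
    t, L = scenario.terminus, scenario.cos_overhang
    cls = scenario.phage_class
    if cls == "cos5":
        return {"left": t + 1, "right": t + L}
    if cls == "cos3":
        return {"left": t + L + 1, "right": t}
    if cls == "dtr":
        return {"left": t + 1, "right": t + scenario.dtr_length}
    if cls == "pac":
        sites = scenario.pac_sites or [(t, 1.0)]
        return {"left": sites[0][0] + 1, "right": None}
    return {"left": None, "right": None}


@dataclass
class SimResult:
    scenario: SimScenario
    reference: ReferenceGenome  # what the analysis pipeline should be given
    host: ReferenceGenome | None
    pairs: list[tuple[ReadRecord, ReadRecord | None]]
    truth: list[TruthRead]
    true_termini: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    @property
    def expected_class(self) -> str:
        return EXPECTED_CALL[self.scenario.phage_class]


def simulate_library(scenario: SimScenario) -> SimResult:
    """Run the full generator: genomes -> particles -> fragments -> reads."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_genome, rng_pack, rng_frag, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    phage_ref, host, info = make_genomes(scenario, rng_genome)
    # packaging always works from the true (single-repeat) genome
    if scenario.phage_class == "dtr" and scenario.duplicated_repeat:
        t = scenario.terminus
        rot = phage_ref.sequence[: scenario.genome_length]
        genome_seq = rot[-t:] + rot[:-t]  # undo the rotation
        genome = ReferenceGenome(id="phage", sequence=genome_seq)
    else:
        genome = phage_ref
    molecules = package_particles(scenario, genome, host, rng_pack)
    fragments = fragment_and_repair(molecules, scenario, rng_frag)
    fragments += _contamination_fragments(scenario, len(fragments), host, rng_frag)
    refs = {"phage": genome.sequence}
    if host is not None:
        refs["host"] = host.sequence
    pairs, truth = build_reads(fragments, scenario, refs, rng_reads)
    return SimResult(
        scenario=scenario,
        reference=phage_ref,
        host=host,
        pairs=pairs,
        truth=truth,
        true_termini=_true_termini(scenario),
        info=info,
    )


def emit_fastq(result: SimResult, outdir, prefix: str = "sim") -> dict:
    """Write FASTQ file(s), reference/host FASTA and the truth log CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    scenario = result.scenario

    def _write_fastq(path, records):
        recs = []
        for rec in records:
            sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
            sr.letter_annotations["phred_quality"] = [40] * len(rec.sequence)
            recs.append(sr)
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fastq")

    r1 = [p[0] for p in result.pairs]
    paths["reads1"] = outdir / f"{prefix}_R1.fastq"
    _write_fastq(paths["reads1"], r1)
    if scenario.paired:
        paths["reads2"] = outdir / f"{prefix}_R2.fastq"
        _write_fastq(paths["reads2"], [p[1] for p in result.pairs])

    paths["reference"] = outdir / f"{prefix}_reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(result.reference.sequence), id=result.reference.id,
                   description=f"simulated {scenario.phage_class} phage")],
        str(paths["reference"]), "fasta",
    )
    if result.host is not None:
        paths["host"] = outdir / f"{prefix}_host.fasta"
        SeqIO.write(
            [SeqRecord(Seq(result.host.sequence), id=result.host.id,
                       description="simulated host")],
            str(paths["host"]), "fasta",
        )

    paths["truth"] = outdir / f"{prefix}_truth.csv"
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["read_id", "mate", "ref", "strand", "start_0based",
                    "true_class", "left_terminus", "right_terminus"])
        tt = result.true_termini
        for tr in result.truth:
            w.writerow([tr.read_id, tr.mate, tr.ref, tr.strand, tr.start,
                        scenario.phage_class, tt.get("left"), tt.get("right")])
    return paths
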