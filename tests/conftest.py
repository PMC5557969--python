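import numpy as np
import pytest

from phage_termini import AnalysisOptions, SimScenario, analyze, simulate_library


def small_scenario(phage_class, seed, **kw):
    """Reduced-size library used by the unit suite: 20 kb genome, ~5000
    fragments (~100x fragment coverage), 400 +/- 60 bp fragments."""
    defaults = dict(
        phage_class=phage_class,
        genome_length=20_000,
        n_fragments=5_000,
        fragment_mean=400.0,
        fragment_sd=60.0,
        read_length=100,
        seed=seed,
    )
    defaults.update(kw)
    return SimScenario(**defaults)


def run_sim(phage_class, seed, options=None, **kw):
    sim = simulate_library(small_scenario(phage_class, seed, **kw))
    result = analyze(sim.pairs, sim.reference, host=sim.host, options=options)
    return sim, result


@pytest.fixture(scope="session")
def cos3_small():
    return run_sim("cos3", seed=7)


@pytest.fixture(scope="session")
def cos5_small():
    return run_sim("cos5", seed=7)


@pytest.fixture(scope="session")
def dtr_small():
    return run_sim("dtr", seed=7)


@pytest.fixture(scope="session")
def pac_twosite_small():
    """pac phage whose terminase cleaves at two sites 6 bp apart."""
    scenario = small_scenario(
        "pac", seed=7, n_fragments=15_000, pac_sites=[(5000, 1.0), (5006, 1.0)]
    )
    sim = simulate_library(scenario)
    result = analyze(sim.pairs, sim.reference)
    return sim, result


def random_genome(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- oracles

def bruteforce_profiles(alignments, fragments, G):
    """O(G * reads) reimplementation of profile accumulation via naive
    per-position membership tests; independent of the numpy path."""
    spc = {"forward": [0] * G, "reverse": [0] * G}
    cov = {"forward": [0] * G, "reverse": [0] * G}
    fcov = [0] * G
    for a in alignments:
        spc[a.strand][a.start] += 1
        if a.strand == "forward":
            span = range(a.start, min(a.start + a.read_length, G))
        else:
            span = range(max(a.start - a.read_length + 1, 0), a.start + 1)
        for i in span:
            cov[a.strand][i] += 1
    for f in fragments:
        for i in range(f.left, min(f.right, G)):
            fcov[i] += 1
    return spc, cov, fcov


def bruteforce_scan(ref_seq, read_seq):
    """All exact full-length placements of a read on either strand,
    reported in the mapper's start convention."""
    from phage_termini import revcomp

    hits = []
    start = ref_seq.find(read_seq)
    while start != -1:
        hits.append(("forward", start))
        start = ref_seq.find(read_seq, start + 1)
    rc = revcomp(read_seq)
    start = ref_seq.find(rc)
    while start != -1:
        hits.append(("reverse", start + len(read_seq) - 1))
        start = ref_seq.find(rc, start + 1)
    return hits
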