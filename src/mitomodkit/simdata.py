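"""Synthetic-data generators with machine-readable ground truth.

Provides every upstream input the pipeline consumes without downloads:
references (FASTA), aligned reads (sorted SAM) carrying a programmable
single-site modification signature, multi-species genotype panels, and
logistic growth curves with a noisy proportional fluorescent reporter.

The read generator emulates what reverse transcription of an m1A site looks
like after sequencing: at the site, reads carry A, T or G according to a
misincorporation mixture (A->T dominating, A->G rarer), and a fraction of
site-covering reads arrest at the site, thinning local coverage; elsewhere
errors are uniform. Defaults mirror the study conditions: 50-nt single-end
reads, target depth 2000, p_T = 0.60 / p_G = 0.12 (~72% non-reference, the
total-RNA level), truncation 0.10 (a slight coverage dip), balanced strands.

Every generator is seed-deterministic; truth records are serializable JSON
stamped with the package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pysam

from . import __version__
from .growth_translation import KineticsTable

GENERATOR_VERSION = __version__

_READ_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SiteSignatureSpec:
    """Parameters of the single-site modification signature."""

    pos: int                       # 1-based site on the reference
    p_T: float = 0.60              # A->T misincorporation probability
    p_G: float = 0.12              # A->G misincorporation probability
    p_trunc: float = 0.10          # probability a site-covering read arrests at the site
    strand_split: float = 0.5      # fraction of + strand reads
    seq_error: float = 0.001       # uniform per-base error rate away from the site
    coverage: int = 2000           # target depth
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_T", "p_G", "p_trunc", "strand_split", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_T + self.p_G > 1.0:
            raise ValueError("p_T + p_G must not exceed 1")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")


@dataclass
class TruthRecord:
    """Realized ground truth of one read simulation."""

    spec: SiteSignatureSpec
    site_counts: dict[str, dict[str, int]]   # strand -> base -> count (as aligned)
    site_coverage: int
    flank_median_coverage: float
    n_reads: int
    generator_version: str = GENERATOR_VERSION

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["spec"] = SiteSignatureSpec(**d["spec"])
        return cls(**d)


def make_reference(
    length: int,
    gc_fraction: float = 0.44,
    seed: int = 0,
    embed: tuple[str, int] | None = None,
    name: str = "synthetic_ref",
) -> dict[str, str]:
    """Reproducible pseudo-random DNA reference, optionally with an embedded motif.

    ``embed=(motif, pos)`` places ``motif`` (DNA; U is converted to T) with
    its first base at 1-based ``pos``. GC content defaults to 0.44, the
    neighbourhood of mammalian mtDNA.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    seq = rng.choice(_READ_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    if embed is not None:
        motif, pos = embed
        motif = motif.upper().replace("U", "T")
        if pos < 1 or pos + len(motif) - 1 > length:
            raise ValueError("embedded motif does not fit in the reference")
        seq[pos - 1: pos - 1 + len(motif)] = list(motif)
    return {name: "".join(seq)}


def simulate_reads(
    reference: dict[str, str] | str,
    spec: SiteSignatureSpec,
    sam_path=None,
    rt_stop_directional: bool = False,
) -> tuple[str, TruthRecord]:
    """Simulate aligned reads with a single-site m1A-like signature.

    Reads start uniformly along the reference at the target depth. At the
    site, the emitted base is drawn from (1 - p_T - p_G, p_T, p_G) over
    (A, T, G) before sequencing error; with probability ``p_trunc`` a
    site-covering read arrests at the modification. In the default
    (non-directional) mode the arrest is emitted as a single-base skip of
    the site (reverse transcriptase jumping the blocked base), so flanking
    coverage stays flat and the site's depth is thinned by exactly
    ``p_trunc`` in expectation. With ``rt_stop_directional`` the read is
    instead clipped where cDNA synthesis stops (5' of the site in synthesis
    direction), reproducing the one-sided coverage shoulder of strand-aware
    RT-stop protocols. Uniform errors are applied everywhere else. Reads
    carry valid CIGARs and constant Q37 qualities, written coordinate-sorted.

    Returns ``(sam_text, truth)``; when ``sam_path`` is given the SAM is
    also written there.
    """
    refs = reference if isinstance(reference, dict) else {"ref": reference}
    (ref_name, ref_seq), = refs.items()
    ref_len = len(ref_seq)
    L = spec.read_length
    if ref_len < L:
        raise ValueError("reference shorter than the read length")
    if not 1 <= spec.pos <= ref_len:
        raise ValueError("site outside the reference")

    rng = np.random.default_rng(spec.seed)
    n_reads = int(round(spec.coverage * ref_len / L))
    site0 = spec.pos - 1
    min_len = 15  # truncated alignments shorter than this are dropped

    # Each read: (start0, strand, bases, cigar, skip_site); skip_site marks a
    # 1-base deletion of the site in the alignment (arrest in default mode).
    reads: list[tuple[int, str, str, str, bool]] = []
    starts = rng.integers(0, ref_len - L + 1, size=n_reads)
    is_fwd = rng.random(n_reads) < spec.strand_split
    for k in range(n_reads):
        start = int(starts[k])
        end = start + L  # exclusive
        bases = list(ref_seq[start:end])
        covers_site = start <= site0 < end
        skip_site = False
        cigar = None
        if covers_site:
            u = rng.random()
            if u < spec.p_T:
                bases[site0 - start] = "T"
            elif u < spec.p_T + spec.p_G:
                bases[site0 - start] = "G"
            if rng.random() < spec.p_trunc:
                if rt_stop_directional:
                    # synthesis stops at the site; keep the part made so far
                    if is_fwd[k]:
                        bases = bases[: site0 - start]
                    else:
                        bases = bases[site0 - start + 1:]
                        start = site0 + 1
                    if len(bases) < min_len:
                        continue
                else:
                    a = site0 - start          # matched bases before the site
                    b = end - site0 - 1        # matched bases after the site
                    del bases[a]
                    if a == 0:                 # alignment cannot begin with D
                        start = site0 + 1
                    elif b == 0:
                        pass                   # plain shorter match
                    else:
                        cigar = f"{a}M1D{b}M"
                        skip_site = True
                    if len(bases) < min_len:
                        continue
        # uniform sequencing error
        if spec.seq_error > 0 and bases:
            errs = np.flatnonzero(rng.random(len(bases)) < spec.seq_error)
            for i in errs:
                alts = [b for b in "ACGT" if b != bases[i]]
                bases[i] = alts[rng.integers(0, 3)]
        if cigar is None:
            cigar = f"{len(bases)}M"
        reads.append((start, "+" if is_fwd[k] else "-", "".join(bases), cigar, skip_site))

    reads.sort(key=lambda r: r[0])

    # Ground truth: tally aligned bases at the site straight from the reads.
    site_counts = {"+": {b: 0 for b in "ACGT"}, "-": {b: 0 for b in "ACGT"}}
    cov = np.zeros(ref_len, dtype=int)
    for start, strand, bases, cigar, skip_site in reads:
        if skip_site:
            a = site0 - start
            cov[start: site0] += 1
            cov[site0 + 1: site0 + 1 + (len(bases) - a)] += 1
        else:
            cov[start: start + len(bases)] += 1
            if start <= site0 < start + len(bases):
                site_counts[strand][bases[site0 - start]] += 1
    flank = [cov[p] for p in range(max(0, site0 - 25), min(ref_len, site0 + 26))
             if p != site0 and cov[p] > 0]
    truth = TruthRecord(
        spec=spec,
        site_counts=site_counts,
        site_coverage=int(cov[site0]),
        flank_median_coverage=float(np.median(flank)) if flank else 0.0,
        n_reads=len(reads))

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
        "PG": [{"ID": "mitomodkit-sim", "PN": "mitomodkit",
                "VN": GENERATOR_VERSION}],
    })
    segments = []
    for idx, (start, strand, bases, cigar, _skip) in enumerate(reads):
        a = pysam.AlignedSegment(header)
        a.query_name = f"sim{idx:07d}"
        a.query_sequence = bases
        a.flag = 16 if strand == "-" else 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_qualities = pysam.qualitystring_to_array("F" * len(bases))  # Q37
        segments.append(a)
    sam_text = str(header) + "".join(seg.to_string() + "\n" for seg in segments)
    if sam_path is not None:
        with open(sam_path, "w") as fh:
            fh.write(sam_text)
    return sam_text, truth


def simulate_panel(
    species_specs: list[dict],
    ref_length: int = 400,
    seed: int = 0,
) -> list[dict]:
    """Multi-species panel: per species, a reference, genotype and reads.

    Each entry of ``species_specs`` is a dict with keys ``species``,
    ``genotype`` ("A" or "T" at the site) and optionally any
    :class:`SiteSignatureSpec` field; A-genotype species default to the
    modified-site signature, T-genotype species to no signature. Returns a
    list of dicts with keys species, genotype, reference, site, sam, truth.
    """
    out = []
    site = ref_length // 2
    for i, entry in enumerate(sorted(species_specs, key=lambda e: e["species"])):
        genotype = entry["genotype"].upper()
        if genotype not in ("A", "T"):
            raise ValueError("panel genotype must be A or T")
        sp_seed = (seed * 10007 + i * 101) % (2**31)
        ref = make_reference(ref_length, seed=sp_seed,
                             embed=(genotype, site), name=entry["species"])
        overrides = {k: v for k, v in entry.items() if k not in ("species", "genotype")}
        if genotype == "T":
            overrides.setdefault("p_T", 0.0)
            overrides.setdefault("p_G", 0.0)
            overrides.setdefault("p_trunc", 0.0)
        spec = SiteSignatureSpec(pos=site, seed=sp_seed + 1, **overrides)
        sam, truth = simulate_reads(ref, spec)
        out.append({"species": entry["species"], "genotype": genotype,
                    "reference": ref, "site": site, "sam": sam, "truth": truth})
    return out


def simulate_kinetics(
    K: float = 1.5,
    r: float = 0.02,
    lag: float = 120.0,
    prod_rate: float = 100.0,
    noise_sd: float = 0.0,
    n_replicates: int = 42,
    seed: int = 0,
    od0: float = 0.015,
    t_max: float = 720.0,
    dt: float = 30.0,
) -> tuple[list[KineticsTable], dict]:
    """Logistic growth with a noisy proportional fluorescent reporter.

    OD follows a logistic curve (carrying capacity ``K``, rate ``r`` per
    minute, initial ``od0``) after a lag of ``lag`` minutes. Fluorescence
    accumulates as dF = prod_rate * OD_t * dt + N(0, noise_sd) per sampling
    interval, so the per-minute production rate recovered by
    :func:`~mitomodkit.growth_translation.production_rate` (divided by dt)
    equals ``prod_rate`` in the noise-free case. Defaults reflect plate
    growth sampled every 30 min with 42 replicates.
    """
    if K <= 0 or r <= 0:
        raise ValueError("K and r must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, t_max + dt / 2, dt)
    shifted = np.maximum(t - lag, 0.0)
    od = K * od0 * np.exp(r * shifted) / (K - od0 + od0 * np.exp(r * shifted))
    tables = []
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed * 100003 + rep) % (2**31))
        incr = prod_rate * od[1:] * dt
        if noise_sd > 0:
            incr = incr + rng.normal(0.0, noise_sd, size=incr.shape)
        fluo = np.concatenate([[0.0], np.cumsum(incr)])
        tables.append(KineticsTable(time=t.copy(), od=od.copy(), fluo=fluo,
                                    replicate_id=f"rep{rep + 1}"))
    truth = {"K": K, "r": r, "lag": lag, "prod_rate": prod_rate,
             "noise_sd": noise_sd, "n_replicates": n_replicates,
             "dt": dt, "seed": seed, "generator_version": GENERATOR_VERSION}
    return tables, truth
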