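"""Synthetic genomes with planted TE copies at known divergence.

The generator emulates every input the pipeline consumes — genome FASTA,
RepeatMasker-style ``.out``/``.align`` files, TE consensus library, gene
GFF3, CpG-island BED, recombination-map TSV and a chromosome-size table —
together with a truth table of the planted copies, so the whole analysis
is testable without any real data.

Design:

* Copies are evolved from their consensus by per-site categorical
  substitution sampling with transition:transversion odds ``kappa : 1``
  and a ``cpg_multiplier``-fold transition rate in CpG context.  The base
  rate is calibrated numerically so the *expected* CpG-adjusted K2P
  divergence of the resulting alignment equals the requested ``K_true``;
  truth alignments are gapless.
* LTR retrotransposons are planted as full LTR-internal-LTR structures
  (three hits, distinct run IDs) or solo LTRs; LINEs are 5'-truncated with
  a configurable probability.
* Nested insertions split the host copy into two fragments that share the
  host's run ID and carry correct consensus coordinates.
* Each chromosome carries a smoothed latent field; monotone links from
  that field set local TE insertion intensity, gene density, CpG-island
  density, recombination rate and background GC, so rank associations of
  chosen sign are planted between TE coverage and the feature tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .divergence import kimura2_from_pq
from .io_formats import (
    AlignmentBlock,
    ConsensusRecord,
    IntervalTrack,
    RepeatHit,
    write_bed,
    write_chrom_sizes,
    write_genes_gff3,
    write_library,
    write_recmap,
    write_rm_align,
    write_rm_out,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CopySpec:
    """One planted family: how many copies at which divergence.

    ``k_dist`` is ``("burst", scale)`` (exponential, a recent expansion),
    ``("uniform", lo, hi)`` or ``("fixed", K)``.  ``structure`` is
    ``simple``, ``ltr_full`` (LTR-internal-LTR) or ``ltr_solo``.
    """

    family: str
    n: int
    k_dist: tuple
    structure: str = "simple"
    truncate_5p: bool = False


@dataclass
class Coupling:
    """Monotone link strengths between the latent field and the tracks.

    The planted rank-association sign between TE coverage and a feature is
    the sign of the product of the TE coefficient and that feature's
    coefficient; zero on either side plants independence.  ``te_recent``
    and ``te_ancient`` default to ``te`` when None.
    """

    te: float = 0.5
    te_recent: float | None = None
    te_ancient: float | None = None
    gene: float = -0.3
    cpg: float = 0.2
    rec: float = -0.5
    gc: float = 0.3

    def te_for(self, age_class: str) -> float:
        if age_class == "recent" and self.te_recent is not None:
            return self.te_recent
        if age_class == "ancient" and self.te_ancient is not None:
            return self.te_ancient
        return self.te


def _default_chroms() -> dict:
    return {
        "chr1": 1_200_000,
        "chr2": 900_000,
        "chr3": 600_000,
        "chr4": 400_000,
        "chr5": 250_000,
        "chr6": 150_000,
        "chrZ": 500_000,
    }


def _default_copy_spec() -> list:
    return [
        CopySpec("ERVK1", 40, ("burst", 1.0), structure="ltr_full"),
        CopySpec("LTR2", 15, ("uniform", 4.0, 18.0), structure="ltr_full"),
        CopySpec("LTR2", 20, ("uniform", 4.0, 18.0), structure="ltr_solo"),
        CopySpec("CR1L1", 100, ("uniform", 5.0, 25.0), truncate_5p=True),
        CopySpec("CR1L2", 50, ("uniform", 8.0, 28.0), truncate_5p=True),
        CopySpec("SINE1", 50, ("uniform", 3.0, 20.0)),
        CopySpec("hAT1", 30, ("uniform", 5.0, 22.0)),
    ]


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset.

    Defaults sketch a scaled-down songbird-like genome: a few Mb across
    macro- and micro-like chromosomes plus a Z, ~45% GC, an ERVK-like LTR
    burst near K=1 over broad older LINE activity, kappa = 2 transition
    bias and 10-fold CpG transition acceleration.  A fixed seed makes all
    outputs byte-identical.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=_default_chroms)
    sex_chroms: tuple = ("chrZ",)
    macro_threshold: int = 500_000  # scaled-down macro/micro convention
    gc_background: float = 0.45
    ltr_len: int = 350
    ltr_internal_len: int = 4000
    line_len: int = 4500
    sine_len: int = 150
    dna_len: int = 800
    copy_spec: list = field(default_factory=_default_copy_spec)
    kappa: float = 2.0
    cpg_multiplier: float = 10.0
    truncation_prob: float = 0.8
    truncation_keep_min: float = 0.2
    nesting_prob: float = 0.1
    coupling: Coupling = field(default_factory=Coupling)
    field_window: int = 50_000
    smooth_width: int = 5
    recent_threshold_K: float = 7.0
    gene_density: float = 0.25
    cpg_density: float = 0.02
    rec_base_rate: float = 4.6e-9

    def __post_init__(self) -> None:
        for p in (self.truncation_prob, self.nesting_prob, self.gc_background):
            if not 0 <= p <= 1:
                raise ValueError("probability outside [0, 1]")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("non-positive chromosome length")

    @property
    def genome_len(self) -> int:
        return sum(self.chrom_lengths.values())

    def chrom_meta(self) -> dict:
        return {
            chrom: {"length": L, "is_autosome": chrom not in self.sex_chroms}
            for chrom, L in self.chrom_lengths.items()
        }


# ---------------------------------------------------------------------------
# sequence evolution with calibrated divergence
# ---------------------------------------------------------------------------

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _cpg_flags(consensus: str) -> np.ndarray:
    arr = np.frombuffer(consensus.encode(), dtype="S1")
    flags = np.zeros(len(consensus), dtype=bool)
    cg = (arr[:-1] == b"C") & (arr[1:] == b"G")
    flags[:-1] |= cg
    flags[1:] |= cg
    return flags


def _expected_adjusted_k(p: float, L: int, n_pairs: int, kappa: float, m: float):
    """Expected CpG-adjusted K2P (%) under the per-site substitution model."""
    t = p * kappa / (kappa + 1.0)
    q = p / (kappa + 1.0)
    c = min(m * t, 1.0 - q - 1e-9)
    e_pair = c * c + 0.2 * c * (1.0 - c)
    n1 = L - 2 * n_pairs
    P = (n1 * t + n_pairs * e_pair) / L
    return kimura2_from_pq(P, q)


def _calibrate_rate(
    K_true: float, L: int, n_pairs: int, kappa: float, m: float
) -> float:
    """Bisect the base substitution probability so E[adjusted K] = K_true."""
    if K_true == 0:
        return 0.0
    lo, hi = 0.0, 0.75
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        try:
            val = _expected_adjusted_k(mid, L, n_pairs, kappa, m)
        except ValueError:  # saturated: overshoot
            val = math.inf
        if val > K_true:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def evolve_copy(
    consensus: str,
    K_true: float,
    kappa: float,
    cpg_multiplier: float,
    rng: np.random.Generator,
):
    """Mutate a consensus so the expected adjusted K2P divergence is K_true.

    Returns ``(sequence, (query_aln, cons_aln), counts)`` with a gapless
    truth alignment and realized ``{"ts", "tv", "n_sites"}`` counts.
    """
    if not 0 <= K_true < 50:
        raise ValueError("K_true outside [0, 50)")
    if len(consensus) < 50:
        raise ValueError("consensus shorter than 50 bp")
    L = len(consensus)
    flags = _cpg_flags(consensus)
    n_pairs = int(flags.sum()) // 2
    p = _calibrate_rate(K_true, L, n_pairs, kappa, cpg_multiplier)
    t = p * kappa / (kappa + 1.0)
    q = p / (kappa + 1.0)
    c = min(cpg_multiplier * t, 1.0 - q - 1e-9)
    t_site = np.where(flags, c, t)
    r = rng.random(L)
    is_ts = r < t_site
    is_tv = (~is_ts) & (r < t_site + q)
    tv_pick = rng.random(L) < 0.5
    out = list(consensus)
    ts_n = tv_n = 0
    for i in np.nonzero(is_ts | is_tv)[0]:
        base = consensus[i]
        if is_ts[i]:
            out[i] = _TS[base]
            ts_n += 1
        else:
            out[i] = _TV[base][int(tv_pick[i])]
            tv_n += 1
    seq = "".join(out)
    counts = {"ts": ts_n, "tv": tv_n, "n_sites": L}
    return seq, (seq, consensus), counts


# ---------------------------------------------------------------------------
# latent field and feature tracks
# ---------------------------------------------------------------------------


def smoothed_field(n: int, rng: np.random.Generator, width: int = 5) -> np.ndarray:
    """Standardized moving-average-smoothed Gaussian field of length n."""
    if n <= 0:
        return np.zeros(0)
    raw = rng.standard_normal(n + width - 1)
    kernel = np.ones(width) / width
    u = np.convolve(raw, kernel, mode="valid")
    sd = u.std()
    return (u - u.mean()) / sd if sd > 0 else u * 0.0


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _intensity_weights(u: np.ndarray, a: float) -> np.ndarray:
    return _softmax(a * u) if len(u) else u


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


@dataclass
class _Fragment:
    family: str
    class_family: str
    strand: str
    offset: int  # within the element's composite slot
    seq: str  # genomic orientation
    qaln: str  # consensus orientation (mutated)
    caln: str  # consensus orientation
    cons_start: int
    cons_end: int
    cons_left: int
    run_id: int = -1

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class _Element:
    copy_id: str
    family: str
    class_label: str
    strand: str
    K_true: float
    fragments: list
    total_len: int
    age_class: str
    nested_in: str = ""
    chrom: str = ""
    start: int = -1


def build_library(config: SimConfig, rng: np.random.Generator) -> dict:
    """Random consensus library covering the configured families."""

    def rand_seq(n: int) -> str:
        gc = 0.45
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])

    lib: dict = {}
    seen = set()
    for spec in config.copy_spec:
        if spec.family in seen:
            continue
        seen.add(spec.family)
        fam = spec.family
        if spec.structure in ("ltr_full", "ltr_solo"):
            for suffix, n, cf in (
                ("_LTR", config.ltr_len, f"LTR/{fam}"),
                ("_I", config.ltr_internal_len, f"LTR/{fam}"),
            ):
                name = fam + suffix
                if name not in lib:
                    lib[name] = ConsensusRecord(name, cf, rand_seq(n))
        else:
            if fam.startswith("CR1") or fam.startswith("LINE"):
                n, cf = config.line_len, "LINE/CR1"
            elif fam.startswith("SINE"):
                n, cf = config.sine_len, "SINE/tRNA"
            elif fam.startswith("hAT") or fam.startswith("DNA"):
                n, cf = config.dna_len, "DNA/hAT"
            else:
                n, cf = config.line_len, "Unknown"
            lib[fam] = ConsensusRecord(fam, cf, rand_seq(n))
    return lib


def _draw_k(k_dist: tuple, rng: np.random.Generator) -> float:
    kind = k_dist[0]
    if kind == "burst":
        return float(min(rng.exponential(k_dist[1]), 6.0))
    if kind == "uniform":
        return float(rng.uniform(k_dist[1], k_dist[2]))
    if kind == "fixed":
        return float(k_dist[1])
    raise ValueError(f"unknown divergence distribution {kind!r}")


def _make_part(
    rec: ConsensusRecord,
    strand: str,
    K_true: float,
    config: SimConfig,
    rng: np.random.Generator,
    keep_frac: float = 1.0,
) -> _Fragment:
    cons = rec.sequence
    clen = len(cons)
    if keep_frac < 1.0:
        keep = max(60, int(round(keep_frac * clen)))
        cons_start = clen - keep + 1  # 5' truncation keeps the 3' end
    else:
        cons_start = 1
    cons_end = clen
    sub = cons[cons_start - 1 : cons_end]
    mutated, (qaln, caln), _ = evolve_copy(
        sub, K_true, config.kappa, config.cpg_multiplier, rng
    )
    genomic = mutated if strand == "+" else revcomp(mutated)
    return _Fragment(
        family=rec.name,
        class_family=rec.class_family,
        strand=strand,
        offset=0,
        seq=genomic,
        qaln=qaln,
        caln=caln,
        cons_start=cons_start,
        cons_end=cons_end,
        cons_left=0,
    )


def _plan_elements(config: SimConfig, lib: dict, rng: np.random.Generator) -> list:
    elements = []
    counter = 0
    for spec in config.copy_spec:
        for _ in range(spec.n):
            K_true = _draw_k(spec.k_dist, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            cid = f"planted_{counter:05d}"
            counter += 1
            if spec.structure == "ltr_full":
                ltr = lib[spec.family + "_LTR"]
                internal = lib[spec.family + "_I"]
                parts = [
                    _make_part(ltr, strand, K_true, config, rng),
                    _make_part(internal, strand, K_true, config, rng),
                    _make_part(ltr, strand, K_true, config, rng),
                ]
                if strand == "-":
                    parts = parts[::-1]
            elif spec.structure == "ltr_solo":
                parts = [_make_part(lib[spec.family + "_LTR"], strand, K_true, config, rng)]
            else:
                keep = 1.0
                if spec.truncate_5p and rng.random() < config.truncation_prob:
                    keep = float(rng.uniform(config.truncation_keep_min, 1.0))
                parts = [_make_part(lib[spec.family], strand, K_true, config, rng, keep)]
            off = 0
            for p in parts:
                p.offset = off
                off += p.length
            age = "recent" if K_true <= config.recent_threshold_K else "ancient"
            elements.append(
                _Element(
                    copy_id=cid,
                    family=spec.family,
                    class_label=lib[parts[0].family].class_label,
                    strand=strand,
                    K_true=K_true,
                    fragments=parts,
                    total_len=off,
                    age_class=age,
                )
            )
    return elements


def _split_host(host: _Element, nested: _Element, rng: np.random.Generator) -> None:
    """Insert ``nested`` inside ``host``'s single fragment, splitting it."""
    frag = host.fragments[0]
    hl = frag.length
    cut = int(rng.integers(100, hl - 100))
    left_seq, right_seq = frag.seq[:cut], frag.seq[cut:]
    # consensus-orientation cut position mirrors the genomic cut on "-"
    ccut = cut if frag.strand == "+" else hl - cut
    if frag.strand == "+":
        left = replace(
            frag,
            seq=left_seq,
            qaln=frag.qaln[:ccut],
            caln=frag.caln[:ccut],
            cons_end=frag.cons_start + ccut - 1,
        )
        right = replace(
            frag,
            seq=right_seq,
            qaln=frag.qaln[ccut:],
            caln=frag.caln[ccut:],
            cons_start=frag.cons_start + ccut,
        )
    else:
        # left genomic fragment is the 3' end of the consensus
        left = replace(
            frag,
            seq=left_seq,
            qaln=frag.qaln[ccut:],
            caln=frag.caln[ccut:],
            cons_start=frag.cons_start + ccut,
        )
        right = replace(
            frag,
            seq=right_seq,
            qaln=frag.qaln[:ccut],
            caln=frag.caln[:ccut],
            cons_end=frag.cons_start + ccut - 1,
        )
    left.offset = 0
    for p in nested.fragments:
        p.offset += cut
    right.offset = cut + nested.total_len
    host.fragments = [left, right]
    host.total_len = hl + nested.total_len
    nested.nested_in = host.copy_id


def plant_genome(config: SimConfig, outdir=None) -> "SyntheticDataset":
    """Generate the full synthetic dataset (optionally writing all files).

    Raises when the requested copies would fill more than 80% of the
    genome.  With a fixed seed the in-memory objects and every written
    file are byte-identical between runs.
    """
    rng = np.random.default_rng(config.seed)
    lib = build_library(config, rng)
    elements = _plan_elements(config, lib, rng)
    total_te = sum(e.total_len for e in elements)
    if total_te > 0.8 * config.genome_len:
        raise ValueError("overfull genome")

    # nesting: single-fragment elements may land inside a larger simple host
    hosts = [
        e
        for e in elements
        if len(e.fragments) == 1 and e.total_len >= 1000 and not e.nested_in
    ]
    nested_ids = set()
    used_hosts = set()
    for e in elements:
        if len(e.fragments) != 1 or e.total_len > 600:
            continue
        if rng.random() >= config.nesting_prob:
            continue
        candidates = [
            h
            for h in hosts
            if h.copy_id not in used_hosts
            and h.copy_id != e.copy_id
            and h.total_len >= e.total_len + 400
        ]
        if not candidates:
            continue
        host = candidates[int(rng.integers(len(candidates)))]
        _split_host(host, e, rng)
        nested_ids.add(e.copy_id)
        used_hosts.add(host.copy_id)

    # latent fields and placement
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    fields = {}
    for c in chroms:
        n_windows = max(1, config.chrom_lengths[c] // config.field_window)
        fields[c] = smoothed_field(n_windows, rng, config.smooth_width)

    occupied: dict = {c: [] for c in chroms}

    def fits(chrom: str, start: int, length: int) -> bool:
        end = start + length
        if end > config.chrom_lengths[chrom]:
            return False
        return all(e0 >= end or e1 <= start for e0, e1 in occupied[chrom])

    placeable = [e for e in elements if e.copy_id not in nested_ids]
    for e in placeable:
        a = config.coupling.te_for(e.age_class)
        placed = False
        for _ in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            u = fields[chrom]
            w = _intensity_weights(u, a)
            widx = int(rng.choice(len(w), p=w))
            wlo = widx * config.field_window
            whi = min(wlo + config.field_window, config.chrom_lengths[chrom])
            start = int(rng.integers(wlo, whi))
            if fits(chrom, start, e.total_len):
                occupied[chrom].append((start, start + e.total_len))
                e.chrom, e.start = chrom, start
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place element {e.copy_id}; genome too full")
    for e in elements:
        if e.copy_id in nested_ids:
            host = next(h for h in elements if h.copy_id == e.nested_in)
            e.chrom = host.chrom
            e.start = host.start + host.fragments[0].length

    # assign run IDs in genomic order of each element's first fragment
    # (e.start is that genomic position for nested and top-level alike).
    # Fragments produced by nesting splits share their element's ID, but
    # the LTR / internal parts of a full LTR structure each get their own,
    # as RepeatMasker reports them as separate runs.
    order = sorted(elements, key=lambda e: (e.chrom, e.start))
    run_counter = 1
    for e in order:
        is_ltr_structure = len({f.family for f in e.fragments}) > 1
        for f in e.fragments:
            f.run_id = run_counter
            if is_ltr_structure:
                run_counter += 1
        if not is_ltr_structure:
            run_counter += 1

    # background sequences with per-window GC tied to the latent field
    sequences = {}
    bases = np.array(list("ACGT"))
    for c in chroms:
        L = config.chrom_lengths[c]
        u = fields[c]
        parts = []
        for widx in range(max(1, L // config.field_window)):
            wlo = widx * config.field_window
            whi = min(wlo + config.field_window, L)
            if widx == max(1, L // config.field_window) - 1:
                whi = L
            gc = float(
                np.clip(
                    config.gc_background + 0.04 * config.coupling.gc * u[widx],
                    0.25,
                    0.65,
                )
            )
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            parts.append("".join(bases[rng.choice(4, size=whi - wlo, p=p)]))
        seq = list("".join(parts))
        anchors = {e.copy_id: e.start for e in elements if not e.nested_in}
        for e in elements:
            if e.chrom != c:
                continue
            slot = anchors[e.copy_id] if not e.nested_in else anchors[e.nested_in]
            for f in e.fragments:
                seq[slot + f.offset : slot + f.offset + f.length] = f.seq
        sequences[c] = "".join(seq)

    # hits + alignment blocks
    hits, blocks = [], []
    truth_rows = []
    for e in elements:
        slot = e.start if not e.nested_in else None
        if e.nested_in:
            host = next(h for h in elements if h.copy_id == e.nested_in)
            slot = host.start
        frag_ivals = []
        div_sum = 0.0
        for f in e.fragments:
            g0 = slot + f.offset
            g1 = g0 + f.length
            mism = sum(a != b for a, b in zip(f.qaln, f.caln))
            div = 100.0 * mism / len(f.qaln)
            div_sum += div * f.length
            clen = lib[f.family].length
            hit = RepeatHit(
                chrom=e.chrom,
                start=g0,
                end=g1,
                strand=f.strand,
                family_name=f.family,
                class_family=f.class_family,
                score=max(1, int(f.length * 9 * (1 - div / 100))),
                pct_div=round(div, 1),
                pct_del=0.0,
                pct_ins=0.0,
                cons_start=f.cons_start,
                cons_end=f.cons_end,
                cons_left=clen - f.cons_end,
                run_id=f.run_id,
            )
            hits.append(hit)
            blocks.append(AlignmentBlock(hit=hit, query_seq=f.qaln, cons_seq=f.caln))
            frag_ivals.append((g0, g1))
        truth_rows.append(
            {
                "copy_id": e.copy_id,
                "chrom": e.chrom,
                "start": min(s for s, _ in frag_ivals),
                "end": max(t for _, t in frag_ivals),
                "strand": e.strand,
                "family": e.family,
                "class": e.class_label,
                "K_true": round(e.K_true, 4),
                "mean_raw_div": round(div_sum / e.total_len, 4),
                "n_fragments": len(e.fragments),
                "fragments": ";".join(f"{s}-{t}" for s, t in sorted(frag_ivals)),
                "age_class": e.age_class,
                "nested_in": e.nested_in,
            }
        )
    hits.sort(key=lambda h: (h.chrom, h.start))
    key_order = {h.key: i for i, h in enumerate(hits)}
    blocks.sort(key=lambda b: key_order[b.hit.key])
    truth = pd.DataFrame(
        sorted(truth_rows, key=lambda r: (r["chrom"], r["start"]))
    )

    # feature tracks from the same latent fields
    genes, cpg, recmap = [], [], []
    for c in chroms:
        L = config.chrom_lengths[c]
        u = fields[c]
        nw = len(u)
        gw = _intensity_weights(u, config.coupling.gene)
        n_genes = int(L * config.gene_density / 3000)
        for _ in range(n_genes):
            widx = int(rng.choice(nw, p=gw))
            s = int(rng.integers(widx * config.field_window, min((widx + 1) * config.field_window, L)))
            glen = int(np.clip(rng.lognormal(math.log(2500), 0.5), 500, 20000))
            if s + glen <= L:
                genes.append(IntervalTrack(c, s, s + glen))
        cw = _intensity_weights(u, config.coupling.cpg)
        n_cpg = int(L * config.cpg_density / 400)
        for _ in range(n_cpg):
            widx = int(rng.choice(nw, p=cw))
            s = int(rng.integers(widx * config.field_window, min((widx + 1) * config.field_window, L)))
            clen_i = int(np.clip(rng.lognormal(math.log(400), 0.4), 150, 2500))
            if s + clen_i <= L:
                cpg.append(IntervalTrack(c, s, s + clen_i))
        for widx in range(nw):
            wlo = widx * config.field_window
            whi = min((widx + 1) * config.field_window, L) if widx < nw - 1 else L
            rate = config.rec_base_rate * math.exp(
                config.coupling.rec * u[widx] + 0.4 * rng.standard_normal()
            )
            recmap.append(IntervalTrack(c, wlo, whi, rate))
    genes.sort(key=lambda t: (t.chrom, t.start))
    cpg.sort(key=lambda t: (t.chrom, t.start))
    recmap.sort(key=lambda t: (t.chrom, t.start))

    ds = SyntheticDataset(
        config=config,
        library=lib,
        sequences=sequences,
        chrom_meta=config.chrom_meta(),
        hits=hits,
        blocks=blocks,
        genes=genes,
        cpg=cpg,
        recmap=recmap,
        truth=truth,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus optional on-disk copies."""

    config: SimConfig
    library: dict
    sequences: dict
    chrom_meta: dict
    hits: list
    blocks: list
    genes: list
    cpg: list
    recmap: list
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sizes = {c: m["length"] for c, m in self.chrom_meta.items()}
        paths = {
            "genome": outdir / "genome.fa",
            "sizes": outdir / "chrom.sizes",
            "out": outdir / "te.out",
            "align": outdir / "te.align",
            "library": outdir / "library.fa",
            "genes": outdir / "genes.gff3",
            "cpg": outdir / "cpg.bed",
            "recmap": outdir / "recmap.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for c, seq in self.sequences.items():
                fh.write(f">{c}\n")
                for off in range(0, len(seq), 70):
                    fh.write(seq[off : off + 70] + "\n")
        with open(paths["sizes"], "w") as fh:
            write_chrom_sizes(self.chrom_meta, fh)
        with open(paths["out"], "w") as fh:
            write_rm_out(self.hits, fh, sizes)
        with open(paths["align"], "w") as fh:
            write_rm_align(self.blocks, fh, sizes)
        with open(paths["library"], "w") as fh:
            write_library(self.library, fh)
        with open(paths["genes"], "w") as fh:
            write_genes_gff3(self.genes, fh)
        with open(paths["cpg"], "w") as fh:
            write_bed(self.cpg, fh)
        with open(paths["recmap"], "w") as fh:
            write_recmap(self.recmap, fh)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.paths = {k: str(v) for k, v in paths.items()}
        return self.paths


# ---------------------------------------------------------------------------
# window-level correlation sampler (for rank-statistic recovery tests)
# ---------------------------------------------------------------------------


def simulate_window_table(
    n_windows: int,
    coupling: Coupling,
    rng: np.random.Generator,
    n_copies: int = 400,
    mean_copy_bp: float = 2000.0,
    window_bp: int = 200_000,
    noise: float = 0.5,
    smooth_width: int = 5,
) -> pd.DataFrame:
    """Sample a windowed feature table directly from the latent-field model.

    The same monotone-link structure as :func:`plant_genome`, but skipping
    sequence realisation: TE bp are multinomially placed over windows with
    intensity ``exp(a_te * u)``, features are monotone transforms of the
    field plus independent noise.  Used for calibrating and testing the
    rank statistics at realistic window counts.
    """

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    u = smoothed_field(n_windows, rng, smooth_width)
    eps = rng.standard_normal

    def place(a: float, n: int) -> np.ndarray:
        w = _intensity_weights(u, a)
        counts = rng.multinomial(n, w)
        bp = counts * mean_copy_bp * np.exp(0.2 * eps(n_windows))
        return np.minimum(100.0, 100.0 * bp / window_bp)

    half = n_copies // 2
    te_recent = place(coupling.te_for("recent"), half)
    te_ancient = place(coupling.te_for("ancient"), n_copies - half)
    table = pd.DataFrame(
        {
            "te_cov_recent": te_recent,
            "te_cov_ancient": te_ancient,
            "te_cov_all": np.minimum(100.0, te_recent + te_ancient),
            "gene_cov": 100.0 * sig(-1.2 + coupling.gene * u + noise * eps(n_windows)),
            "cpg_cov": 100.0 * sig(-3.0 + coupling.cpg * u + noise * eps(n_windows)),
            "gc": 42.0 + 3.0 * coupling.gc * u + 1.5 * eps(n_windows),
            "rec_rate": 4.6e-9
            * np.exp(coupling.rec * u + noise * eps(n_windows)),
        }
    )
    return table


def plant_correlations(coupling: Coupling) -> dict:
    """Expected sign of each (TE category, feature) rank association.

    The sign is the product of the category's TE coefficient and the
    feature's coefficient; zero on either side means "none".
    """

    def sign(a: float, b: float) -> str:
        s = a * b
        if s > 0:
            return "+"
        if s < 0:
            return "-"
        return "none"

    feats = {"gene_cov": coupling.gene, "cpg_cov": coupling.cpg,
             "gc": coupling.gc, "rec_rate": coupling.rec}
    out = {}
    for cat, a in (
        ("all", coupling.te),
        ("recent", coupling.te_for("recent")),
        ("ancient", coupling.te_for("ancient")),
    ):
        out[cat] = {name: sign(a, b) for name, b in feats.items()}
    return out
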