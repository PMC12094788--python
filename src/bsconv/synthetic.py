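"""Synthetic data generators with recorded ground truth.

Everything the framework consumes can be generated here with known truth:

* an unmethylated control genome report where the non-conversion rate varies
  between windows according to a beta distribution (emulating the chloroplast
  control);
* a methylated genome report with loci in known states (unmethylated,
  gene-body-like, TE-like) plus their BED annotation;
* methylation-tagged SAM reads implementing the nick/strand-displacement
  error mechanism: a nick in the adaptor displaces the whole fragment
  (fully unconverted read), an internal nick displaces everything
  downstream of a random position (partially unconverted read with a 3'
  bias), and a residual per-cytosine failure rate affects clean reads.

All generators are deterministic given a seed and emit files that the
corresponding :mod:`bsconv.io_formats` readers parse back exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from bsconv.error_profile import BetaErrorModel
from bsconv.io_formats import (
    CytosineSiteRecord,
    STRAND_CLASSES,
    write_cytosine_report,
)

#: Trinucleotides consistent with each context (2nd base G <=> CG;
#: 3rd base G and 2nd base not G <=> CHG; else CHH).
_CONTEXT_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}

#: XM call characters per context (upper = unconverted).
_CONTEXT_XM = {"CG": ("Z", "z"), "CHG": ("X", "x"), "CHH": ("H", "h")}

_STRAND_TAGS = {  # strand class -> (XG, XR)
    "OT": ("CT", "CT"),
    "CTOT": ("CT", "GA"),
    "OB": ("GA", "CT"),
    "CTOB": ("GA", "GA"),
}


@dataclass
class FixtureTruth:
    """Ground truth recorded by a generator, keyed by what it emitted.

    ``window_eps`` — per-window true non-conversion rate (control report);
    ``loci`` — per-locus state and per-context theta/eps (state report);
    ``reads`` — per-read category and nick offset (tagged reads).
    """

    window_eps: Optional[np.ndarray] = None
    loci: Optional[pd.DataFrame] = None
    reads: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class NickModelParams:
    """Parameters of the nick/strand-displacement error mechanism.

    ``q_full`` — probability the adaptor is nicked and the whole fragment
    displaced (read fully unconverted); ``q_nick`` — probability of a single
    internal nick at a uniform position, displacing all downstream cytosines;
    ``base_conversion_failure`` — residual per-cytosine non-conversion on
    otherwise clean (undisplaced) sequence.
    """

    q_full: float = 0.15
    q_nick: float = 0.15
    base_conversion_failure: float = 0.005
    gc_biased_nicks: bool = False

    def __post_init__(self) -> None:
        for name in ("q_full", "q_nick", "base_conversion_failure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.q_full + self.q_nick > 1.0:
            raise ValueError("q_full + q_nick must be <= 1")


def _context_cycle(i: int) -> str:
    return ("CG", "CHG", "CHH")[i % 3]


def make_control_report(
    path: str | Path,
    n_windows: int = 100,
    window_size: int = 150,
    sites_per_window: int = 10,
    coverage: int = 50,
    error_model: BetaErrorModel = BetaErrorModel(17.0, 220.0),
    seed: int = 0,
    chrom: str = "ctrl",
) -> FixtureTruth:
    """Write a cytosine report for an unmethylated control with windowed errors.

    One error rate per window is drawn from ``error_model``; every site in
    the window then draws its unconverted count binomially at that rate.
    Sites are evenly spaced within windows and cycle through the three
    contexts.
    """
    if min(n_windows, window_size, sites_per_window, coverage) < 1:
        raise ValueError("all counts must be >= 1")
    if sites_per_window > window_size:
        raise ValueError("sites_per_window cannot exceed window_size")
    rng = np.random.default_rng(seed)
    eps = error_model.rvs(n_windows, rng)
    spacing = window_size // sites_per_window
    records = []
    for w in range(n_windows):
        base = w * window_size
        meth = rng.binomial(coverage, eps[w], size=sites_per_window)
        for s in range(sites_per_window):
            context = _context_cycle(w * sites_per_window + s)
            records.append(
                CytosineSiteRecord(
                    chrom=chrom,
                    pos=base + s * spacing + 1,
                    strand="+",
                    meth_count=int(meth[s]),
                    unmeth_count=coverage - int(meth[s]),
                    context=context,
                    trinucleotide=_CONTEXT_TRINUC[context],
                )
            )
    write_cytosine_report(records, path)
    return FixtureTruth(window_eps=eps)


#: Default true methylation level per state and context: unmethylated loci
#: carry none, gene-body-like loci methylate CG only, TE-like loci all three.
DEFAULT_THETA_BY_STATE: dict[str, dict[str, float]] = {
    "um": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
    "gbm": {"CG": 0.3, "CHG": 0.0, "CHH": 0.0},
    "TEm": {"CG": 0.3, "CHG": 0.3, "CHH": 0.3},
}


def make_state_report(
    report_path: str | Path,
    bed_path: str | Path,
    n_loci_per_state: tuple[int, int, int] = (10, 10, 10),
    sites_per_context: int = 20,
    coverage: int = 50,
    theta_by_state_context: Optional[dict[str, dict[str, float]]] = None,
    error_model: BetaErrorModel = BetaErrorModel(17.0, 220.0),
    seed: int = 0,
    chrom: str = "synth1",
) -> FixtureTruth:
    """Write a cytosine report plus BED loci with known methylation states.

    Each locus draws one non-conversion rate per context from the error
    model; each site's unconverted count is binomial at
    theta + (1 - theta) * eps. Methylated thetas must exceed the error-model
    mean, otherwise the generating states are not separable even in
    principle.
    """
    thetas = theta_by_state_context or DEFAULT_THETA_BY_STATE
    for state, by_ctx in thetas.items():
        for ctx, theta in by_ctx.items():
            if theta > 0.0 and theta <= error_model.mean:
                raise ValueError(
                    f"theta {theta} for {state}/{ctx} does not exceed the "
                    f"error-model mean {error_model.mean:.4f}"
                )
    rng = np.random.default_rng(seed)
    locus_len = sites_per_context * 3 * 4  # sites every 4 bp, 3 contexts
    records = []
    bed_rows = []
    truth_rows = []
    pos_cursor = 0
    locus_idx = 0
    for state, n_state in zip(("um", "gbm", "TEm"), n_loci_per_state):
        for _ in range(n_state):
            locus_id = f"locus_{locus_idx:04d}"
            eps_by_ctx = {
                ctx: float(error_model.rvs(1, rng)[0])
                for ctx in ("CG", "CHG", "CHH")
            }
            offset = 0
            for ctx in ("CG", "CHG", "CHH"):
                theta = thetas[state][ctx]
                p = theta + (1.0 - theta) * eps_by_ctx[ctx]
                meth = rng.binomial(coverage, p, size=sites_per_context)
                for s in range(sites_per_context):
                    records.append(
                        CytosineSiteRecord(
                            chrom=chrom,
                            pos=pos_cursor + offset + s * 4 + 1,
                            strand="+",
                            meth_count=int(meth[s]),
                            unmeth_count=coverage - int(meth[s]),
                            context=ctx,
                            trinucleotide=_CONTEXT_TRINUC[ctx],
                        )
                    )
                offset += sites_per_context * 4
            bed_rows.append((chrom, pos_cursor, pos_cursor + locus_len, locus_id))
            truth_rows.append(
                {
                    "locus_id": locus_id,
                    "state": state,
                    **{f"theta_{c.lower()}": thetas[state][c] for c in ("CG", "CHG", "CHH")},
                    **{f"eps_{c.lower()}": eps_by_ctx[c] for c in ("CG", "CHG", "CHH")},
                }
            )
            pos_cursor += locus_len
            locus_idx += 1
    records.sort(key=lambda r: r.pos)
    write_cytosine_report(records, report_path)
    with Path(bed_path).open("w") as handle:
        for chrom_, start, end, name in bed_rows:
            handle.write(f"{chrom_}\t{start}\t{end}\t{name}\n")
    return FixtureTruth(loci=pd.DataFrame(truth_rows))


def make_tagged_reads(
    path: str | Path,
    n_reads: int = 1000,
    read_length: int = 80,
    cytosine_density: float = 0.2,
    params: NickModelParams = NickModelParams(),
    strand_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    chrom: str = "synth1",
) -> FixtureTruth:
    """Write Bismark-tagged SAM reads generated by the nick model.

    Each read is fully displaced with probability ``q_full``, internally
    nicked at a uniform position with probability ``q_nick`` (cytosines at
    and downstream of the nick unconverted), or clean (each cytosine
    unconverted at the residual failure rate). Strand classes are drawn from
    ``strand_mix`` (uniform by default). With ``gc_biased_nicks`` the nick
    position is weighted towards cytosine positions, emulating Tn5's G/C
    insertion preference.
    """
    if n_reads < 1 or read_length < 1:
        raise ValueError("n_reads and read_length must be >= 1")
    if not (0.0 < cytosine_density <= 1.0):
        raise ValueError("cytosine_density must lie in (0, 1]")
    mix = strand_mix or {sc: 0.25 for sc in STRAND_CLASSES}
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("strand_mix probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": max(10_000, n_reads + read_length)}],
        }
    )
    truth_rows = []
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i in range(n_reads):
            is_cyt = rng.random(read_length) < cytosine_density
            contexts = rng.choice(["CG", "CHG", "CHH"], size=read_length)
            u = rng.random()
            if u < params.q_full:
                category, nick_pos = "full", 0
                unconverted = np.ones(read_length, dtype=bool)
            elif u < params.q_full + params.q_nick:
                category = "nicked"
                if params.gc_biased_nicks:
                    weights = np.where(is_cyt, 3.0, 1.0)
                    nick_pos = int(rng.choice(read_length, p=weights / weights.sum()))
                else:
                    nick_pos = int(rng.integers(read_length))
                unconverted = np.arange(read_length) >= nick_pos
                upstream = np.arange(read_length) < nick_pos
                unconverted = unconverted | (
                    upstream & (rng.random(read_length) < params.base_conversion_failure)
                )
            else:
                category, nick_pos = "clean", -1
                unconverted = rng.random(read_length) < params.base_conversion_failure

            xm = []
            seq = []
            for j in range(read_length):
                if not is_cyt[j]:
                    xm.append(".")
                    seq.append("A")
                else:
                    up, low = _CONTEXT_XM[contexts[j]]
                    if unconverted[j]:
                        xm.append(up)
                        seq.append("C")
                    else:
                        xm.append(low)
                        seq.append("T")
            strand_class = classes[int(rng.choice(len(classes), p=probs))]
            xg, xr = _STRAND_TAGS[strand_class]

            read = pysam.AlignedSegment(header)
            read.query_name = f"read_{i:06d}"
            read.flag = 0
            read.reference_id = 0
            read.reference_start = i
            read.mapping_quality = 42
            read.cigarstring = f"{read_length}M"
            read.query_sequence = "".join(seq)
            read.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            read.set_tags(
                [("XM", "".join(xm)), ("XR", xr), ("XG", xg)]
            )
            sam.write(read)
            truth_rows.append(
                {
                    "read_id": read.query_name,
                    "category": category,
                    "nick_pos": nick_pos,
                    "strand_class": strand_class,
                    "n_cytosines": int(is_cyt.sum()),
                    "n_unconverted": int((is_cyt & unconverted).sum()),
                }
            )
    return FixtureTruth(reads=pd.DataFrame(truth_rows))


def make_genome(
    path: str | Path,
    length: int = 10_000,
    gc_content: float = 0.36,
    seed: int = 0,
    chrom: str = "ctrl",
) -> str:
    """Write a random FASTA genome with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_content <= 1.0):
        raise ValueError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = rng.choice(list("ACGT"), size=length, p=p)
    sequence = "".join(bases)
    with Path(path).open("w") as handle:
        handle.write(f">{chrom}\n")
        for i in range(0, length, 60):
            handle.write(sequence[i : i + 60] + "\n")
    return sequence
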