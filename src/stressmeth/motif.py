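"""DML flank extraction and discriminative k-mer enrichment.

Flanking sequences (position +/- 250 bp by default) around called DMLs are
written as FASTA for external motif discovery tools; an internal check
compares sequence-level k-mer presence (k-mer and reverse complement
collapsed, one count per sequence regardless of occurrences) between the
foreground flanks and a composition-preserving shuffled background with a
one-sided Fisher exact test, Bonferroni-style E-values (p times the number
of distinct k-mers tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# flank extraction

def extract_flanks(
    called_probes: list[str] | pd.Index,
    manifest: pd.DataFrame,
    genome_lengths: dict[str, int] | None = None,
    halfwidth: int = 250,
) -> dict[str, str]:
    """Per-DML flank sequences trimmed to position +/- halfwidth (length
    2*halfwidth + 1 when untruncated; chromosome ends truncate one side with
    a log entry).  Returns an ordered mapping probe id -> sequence."""
    if halfwidth < 1:
        raise ConfigurationError("halfwidth must be >= 1")
    man = manifest.set_index("probe_id")
    records: dict[str, str] = {}
    if len(called_probes) == 0:
        log.warning("no called DMLs; writing an empty flank set")
        return records
    for pid in called_probes:
        if pid not in man.index or not isinstance(man.at[pid, "flank"], str):
            log.warning("probe %s has no stored flank; skipped", pid)
            continue
        flank = man.at[pid, "flank"]
        center = len(flank) // 2
        pos = int(man.at[pid, "pos"])
        left = min(halfwidth, center, pos - 1)
        right = min(halfwidth, len(flank) - 1 - center)
        if genome_lengths is not None:
            chrom_len = genome_lengths.get(str(man.at[pid, "chrom"]))
            if chrom_len is not None:
                right = min(right, chrom_len - pos)
        if left < halfwidth or right < halfwidth:
            log.info("flank for %s truncated to -%d/+%d", pid, left, right)
        records[pid] = flank[center - left : center + right + 1]
    return records


def write_fasta(records: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# background shuffles

def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle: a uniformly random Eulerian walk over the
    dinucleotide multigraph, preserving the dinucleotide count multiset."""
    if len(seq) < 3:
        return seq
    # adjacency lists of the walk graph
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last edge into each vertex (except the terminal vertex),
    # forming a spanning tree toward the terminal; accept when connected
    for _ in range(100):
        lasts = {}
        ok = True
        for v, targets in edges.items():
            if v == last:
                continue
            lasts[v] = targets[int(rng.integers(0, len(targets)))]
        # check the chosen last-edges lead every vertex to the terminal
        for v in edges:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last and u in lasts and u not in seen:
                seen.add(u)
                u = lasts[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # fall back: return the original sequence (composition trivially kept)
        return seq
    out = [seq[0]]
    remaining = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in lasts:
            pool.remove(lasts[v])
        rng.shuffle(pool)
        if v in lasts:
            pool.append(lasts[v])
        remaining[v] = pool
    u = seq[0]
    while remaining.get(u):
        nxt = remaining[u].pop(0)
        out.append(nxt)
        u = nxt
    return "".join(out)


def shuffle_background(
    records: dict[str, str], mode: str = "dinucleotide", seed: int = 0
) -> dict[str, str]:
    """Per-sequence shuffle preserving mononucleotide or dinucleotide
    composition; deterministic per seed."""
    if mode not in ("mononucleotide", "dinucleotide"):
        raise ConfigurationError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = {}
    for name, seq in records.items():
        if mode == "mononucleotide":
            letters = list(seq)
            rng.shuffle(letters)
            out[f"{name}_shuf"] = "".join(letters)
        else:
            if len(seq) < 2:
                out[f"{name}_shuf"] = seq
            else:
                out[f"{name}_shuf"] = _dinucleotide_shuffle(seq, rng)
    return out


# ---------------------------------------------------------------------------
# k-mer enrichment

@dataclass
class KmerResult:
    kmer: str
    k: int
    fg_present: int
    bg_present: int
    fg_total: int
    bg_total: int
    p: float
    e_value: float


def _presence_counts(records: dict[str, str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in records.values():
        seen = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            seen.add(canonical(kmer))
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    foreground: dict[str, str],
    background: dict[str, str],
    k_min: int = 4,
    k_max: int = 8,
    e_cutoff: float = 1e-3,
) -> list[KmerResult]:
    """Fisher one-sided enrichment of sequence-level k-mer presence in the
    foreground vs the background, for every distinct canonical k-mer present
    in the foreground; results with E = p * n_tested below ``e_cutoff``,
    sorted by E ascending (ties by k-mer)."""
    if not 3 <= k_min <= k_max <= 10:
        raise ConfigurationError("need 3 <= k_min <= k_max <= 10")
    if not foreground:
        raise ValueError("foreground is empty")
    if not background:
        raise ValueError("background is empty")
    n_fg = len(foreground)
    n_bg = len(background)
    all_kmers: list[tuple[str, int, int, int]] = []
    for k in range(k_min, k_max + 1):
        fg_counts = _presence_counts(foreground, k)
        bg_counts = _presence_counts(background, k)
        for kmer, a in fg_counts.items():
            all_kmers.append((kmer, k, a, bg_counts.get(kmer, 0)))
    n_tested = len(all_kmers)
    a = np.array([r[2] for r in all_kmers])
    b = np.array([r[3] for r in all_kmers])
    # one-sided Fisher p == hypergeometric upper tail on the 2x2 margins
    p = stats.hypergeom.sf(a - 1, n_fg + n_bg, a + b, n_fg)
    e = p * n_tested
    results = [
        KmerResult(kmer, k, int(fa), int(fb), n_fg, n_bg, float(pp), float(ee))
        for (kmer, k, fa, fb), pp, ee in zip(all_kmers, p, e)
        if ee < e_cutoff
    ]
    results.sort(key=lambda r: (r.e_value, r.kmer))
    return results


def results_to_frame(results: list[KmerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.kmer, r.k, r.fg_present, r.bg_present, r.fg_total, r.bg_total, r.p, r.e_value)
            for r in results
        ],
        columns=["kmer", "k", "fg_present", "bg_present", "fg_total", "bg_total", "p", "e_value"],
    )
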