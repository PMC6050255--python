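"""Permutation enrichment of DMLs over genomic annotations.

Three category systems are tested: gene structures (a probe contributes one
tally per structure annotation it carries), CpG-island relation and
chromosome (one tally per probe).  For structures and island relations the
null draws the DML set's total annotation count from the pooled annotation
multiset of all tested probes, without replacement; for chromosomes the null
draws whole probes and compares per-chromosome *proportions*, by default
family-wise (the actual proportion of a chromosome is compared against the
most extreme permuted proportion of any chromosome, a built-in multiplicity
correction across the 23 chromosomes of an array design).

Enrichment and depletion p-values both include ties (permuted >= / <= actual)
so a degenerate universe yields p = 1 rather than 0; a strict-inequality mode
is available for literal reproduction of the tally rule.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .errors import PipelineError

log = logging.getLogger(__name__)

CATEGORY_TYPES = ("structure", "island_relation", "chromosome")


def tally_annotations(
    dml_probes: list[str] | pd.Index,
    manifest: pd.DataFrame,
    category_type: str,
) -> Counter:
    """Actual per-category counts for a DML set (multiplicity rule for
    structures: every structure a probe carries is tallied)."""
    if category_type not in CATEGORY_TYPES:
        raise ValueError(f"unknown category type {category_type!r}")
    man = manifest.set_index("probe_id")
    missing = [p for p in dml_probes if p not in man.index]
    if missing:
        raise PipelineError(f"probes missing from manifest: {missing[:5]}")
    counts: Counter = Counter()
    for pid in dml_probes:
        if category_type == "structure":
            counts.update(man.at[pid, "structures"])
        elif category_type == "island_relation":
            counts[man.at[pid, "island_relation"]] += 1
        else:
            counts[man.at[pid, "chrom"]] += 1
    return counts


def _tail_p(perm_counts: np.ndarray, actual: float, reps: int, strict: bool, smooth: bool):
    if strict:
        enr = int((perm_counts > actual).sum())
        dep = int((perm_counts < actual).sum())
    else:
        enr = int((perm_counts >= actual).sum())
        dep = int((perm_counts <= actual).sum())
    if smooth:
        return (enr + 1) / (reps + 1), (dep + 1) / (reps + 1)
    return enr / reps, dep / reps


def permute_structures(
    universe_annotations: list[str] | np.ndarray,
    n_draws: int,
    actual_counts: Counter | dict[str, int],
    reps: int = 10_000,
    seed: int = 0,
    strict: bool = False,
    smooth: bool = False,
) -> pd.DataFrame:
    """Sample ``n_draws`` annotations without replacement from the pooled
    multiset ``reps`` times and compare per-category tallies with the actual
    ones."""
    universe = np.asarray(universe_annotations)
    if n_draws > len(universe):
        raise ValueError(f"n_draws={n_draws} exceeds universe size {len(universe)}")
    categories = sorted(set(universe) | set(actual_counts))
    code = {c: i for i, c in enumerate(categories)}
    coded = np.fromiter((code[c] for c in universe), dtype=np.int64, count=len(universe))
    rng = np.random.default_rng(seed)
    perm = np.empty((reps, len(categories)), dtype=np.int64)
    for r in range(reps):
        draw = rng.choice(coded, size=n_draws, replace=False)
        perm[r] = np.bincount(draw, minlength=len(categories))
    rows = []
    for c in categories:
        actual = int(actual_counts.get(c, 0))
        p_enr, p_dep = _tail_p(perm[:, code[c]], actual, reps, strict, smooth)
        rows.append((c, actual, reps, p_enr, p_dep))
    return pd.DataFrame(
        rows, columns=["category", "actual", "reps", "p_enrich", "p_deplete"]
    )


def permute_chromosomes(
    universe_probes: pd.DataFrame,
    n_dml: int,
    actual_counts: Counter | dict[str, int],
    reps: int = 10_000,
    seed: int = 0,
    mode: str = "familywise",
    strict: bool = False,
    smooth: bool = False,
) -> pd.DataFrame:
    """Draw ``n_dml`` probes without replacement and compare per-chromosome
    proportions.  ``mode='familywise'`` compares each chromosome's actual
    proportion against the max (min for depletion) permuted proportion over
    all chromosomes; ``'marginal'`` compares within the same chromosome."""
    if mode not in ("familywise", "marginal"):
        raise ValueError(f"unknown chromosome mode {mode!r}")
    chroms = universe_probes["chrom"].to_numpy()
    categories = sorted(set(chroms))
    for c in actual_counts:
        if c not in categories:
            raise ValueError(f"chromosome {c} absent from the universe")
    code = {c: i for i, c in enumerate(categories)}
    coded = np.fromiter((code[c] for c in chroms), dtype=np.int64, count=len(chroms))
    if n_dml > len(coded):
        raise ValueError("n_dml exceeds the number of tested probes")
    total = sum(actual_counts.values())
    actual_prop = {c: actual_counts.get(c, 0) / total for c in categories}
    rng = np.random.default_rng(seed)
    props = np.empty((reps, len(categories)))
    for r in range(reps):
        draw = rng.choice(coded, size=n_dml, replace=False)
        props[r] = np.bincount(draw, minlength=len(categories)) / n_dml
    rows = []
    pmax = props.max(axis=1)
    pmin = props.min(axis=1)
    for c in categories:
        a = actual_prop[c]
        if mode == "familywise":
            enr_stat, dep_stat = pmax, pmin
        else:
            enr_stat = dep_stat = props[:, code[c]]
        p_enr, p_dep = _tail_p(enr_stat, a, reps, strict, smooth)[0], _tail_p(
            dep_stat, a, reps, strict, smooth
        )[1]
        rows.append((c, a, reps, p_enr, p_dep))
    return pd.DataFrame(
        rows, columns=["category", "actual", "reps", "p_enrich", "p_deplete"]
    )


def pooled_structure_universe(manifest: pd.DataFrame) -> list[str]:
    """The pooled (probe, structure) annotation multiset of all tested
    probes."""
    out: list[str] = []
    for structures in manifest["structures"]:
        out.extend(structures)
    return out


def run_enrichment_suite(
    dml_table: pd.DataFrame,
    manifest: pd.DataFrame,
    reps: int = 10_000,
    seed: int = 0,
    mode: str = "familywise",
    strict: bool = False,
    smooth: bool = False,
) -> pd.DataFrame:
    """All three category types for each DML subset (all / positive /
    negative).  ``dml_table`` is the per-probe call table with ``called`` and
    ``direction`` columns; ``manifest`` covers all tested probes (the
    universe).  Subsets with zero DMLs are skipped with a warning."""
    called = dml_table[dml_table["called"]]
    subsets = {
        "all": called.index,
        "positive": called.index[called["direction"] == "positive"],
        "negative": called.index[called["direction"] == "negative"],
    }
    structure_universe = pooled_structure_universe(manifest)
    island_universe = manifest["island_relation"].to_numpy()
    blocks = []
    rng_root = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_root.spawn(9)]
    si = 0
    for name, ids in subsets.items():
        if len(ids) == 0:
            log.warning("DML subset %r is empty; enrichment block skipped", name)
            si += 3
            continue
        struct_actual = tally_annotations(ids, manifest, "structure")
        res = permute_structures(
            structure_universe,
            n_draws=sum(struct_actual.values()),
            actual_counts=struct_actual,
            reps=reps,
            seed=sub_seeds[si],
            strict=strict,
            smooth=smooth,
        )
        res.insert(0, "category_type", "structure")
        res.insert(0, "subset", name)
        blocks.append(res)
        isl_actual = tally_annotations(ids, manifest, "island_relation")
        res = permute_structures(
            island_universe,
            n_draws=len(ids),
            actual_counts=isl_actual,
            reps=reps,
            seed=sub_seeds[si + 1],
            strict=strict,
            smooth=smooth,
        )
        res.insert(0, "category_type", "island_relation")
        res.insert(0, "subset", name)
        blocks.append(res)
        chrom_actual = tally_annotations(ids, manifest, "chromosome")
        res = permute_chromosomes(
            manifest,
            n_dml=len(ids),
            actual_counts=chrom_actual,
            reps=reps,
            seed=sub_seeds[si + 2],
            mode=mode,
            strict=strict,
            smooth=smooth,
        )
        res.insert(0, "category_type", "chromosome")
        res.insert(0, "subset", name)
        blocks.append(res)
        si += 3
    if not blocks:
        raise PipelineError("no DML subset was non-empty; nothing to permute")
    return pd.concat(blocks, ignore_index=True)
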