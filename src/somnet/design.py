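"""Experimental design grid for the selection time-course.

The experiment tracks six populations (two replicates each of short-,
control- and long-sleeper selection schemes) across 13 sequenced
generations (generation 1 was lost), two sexes, and two replicate RNA
samples per population x generation x sex -- 312 RNA samples in the
default design.  Every downstream count column and phenotype row is
indexed by a record of this manifest.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

SCHEMES = ("short", "control", "long")
#: sequenced generations: 0 and 2..13 (generation-1 RNA was degraded)
DEFAULT_GENERATIONS = (0,) + tuple(range(2, 14))

MANIFEST_COLUMNS = [
    "scheme",
    "population_replicate",
    "generation",
    "sex",
    "rna_replicate",
    "sample_id",
]


def _check_factor(name: str, levels: Sequence) -> list:
    levels = list(levels)
    if not levels:
        raise ValueError(f"factor {name!r} has no levels")
    if len(set(levels)) != len(levels):
        raise ValueError(f"factor {name!r} contains duplicate levels: {levels}")
    return levels


def make_design_manifest(
    schemes: Iterable[str] = SCHEMES,
    pop_replicates: Iterable[int] = (1, 2),
    generations: Iterable[int] = DEFAULT_GENERATIONS,
    sexes: Iterable[str] = ("F", "M"),
    rna_replicates: Iterable[int] = (1, 2),
) -> pd.DataFrame:
    """Build the full-factorial sample manifest.

    Returns a DataFrame with one row per scheme x population replicate x
    generation x sex x RNA replicate combination and a unique ``sample_id``.

    Raises
    ------
    ValueError
        If any factor is empty, contains duplicates, or the generation
        list is not strictly increasing.
    """
    schemes = _check_factor("schemes", schemes)
    pop_replicates = _check_factor("pop_replicates", pop_replicates)
    generations = _check_factor("generations", generations)
    sexes = _check_factor("sexes", sexes)
    rna_replicates = _check_factor("rna_replicates", rna_replicates)
    if list(generations) != sorted(generations):
        raise ValueError("generation list must be strictly increasing")

    records = []
    for scheme in schemes:
        for rep in pop_replicates:
            for gen in generations:
                for sex in sexes:
                    for rr in rna_replicates:
                        sid = f"{scheme}{rep}_g{gen:02d}_{sex}_r{rr}"
                        records.append((scheme, rep, gen, sex, rr, sid))
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    assert manifest["sample_id"].is_unique
    return manifest
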