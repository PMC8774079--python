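"""Packaged fixture tables: transgene specificities, progeny counts, profiles.

``progeny_results.tsv`` transcribes the self-progeny genotype counts
reported for the wild-tomato SLF transgenic lines.  The counts for the
remaining lines (``progeny_synthetic.tsv``) were reported only in
supplementary pollination tables and are packaged here as *synthetic*
stand-ins: representative counts consistent with each line's published
specificity conclusion (a line that inactivates both tester S-RNases
segregates all three genotype classes), not the original data.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from slocus_evo.si_genetics import DetoxSpec

__all__ = [
    "load_transgene_specs",
    "load_progeny_counts",
    "load_species_profiles",
    "PETUNIA_TESTER_ALLELES",
]

#: S-haplotypes of the self-incompatible Petunia hybrida tester genotype
PETUNIA_TESTER_ALLELES: Tuple[str, str] = ("S3", "S3L")


def _read(name: str) -> pd.DataFrame:
    with resources.files("slocus_evo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_transgene_specs() -> List[DetoxSpec]:
    """The 13 cross-taxon transgene specificity calls against S3/S3L."""
    df = _read("transgene_specs.tsv")
    return [
        DetoxSpec(row.transgene_id, frozenset(row.targets.split(",")))
        for row in df.itertuples()
    ]


def load_progeny_counts(include_synthetic: bool = True) -> pd.DataFrame:
    """Per-line progeny genotype counts, long format.

    Columns: line_id, parent_genotype, genotype, count, source
    (``results`` for counts printed in the main text, ``synthetic`` for
    the constructed stand-ins).
    """
    frames = [_read("progeny_results.tsv").assign(source="results")]
    if include_synthetic:
        frames.append(_read("progeny_synthetic.tsv").assign(source="synthetic"))
    return pd.concat(frames, ignore_index=True)


def progeny_counts_by_line(
    include_synthetic: bool = True,
) -> Dict[str, Dict[str, int]]:
    """{line_id: {genotype: count}} convenience view of the progeny table."""
    df = load_progeny_counts(include_synthetic)
    return {
        line: dict(zip(g["genotype"], g["count"]))
        for line, g in df.groupby("line_id", sort=False)
    }


def load_species_profiles() -> pd.DataFrame:
    """The 22-species SI phenotype / type-1 locus inventory table."""
    return _read("species_profiles.tsv")
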