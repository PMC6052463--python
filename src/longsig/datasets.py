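"""Packaged reference inputs.

* the 14-taxon time-calibrated *Drosophila* fixture tree (two subgenera,
  *Sophophora* / *Drosophila*, root depth 56 My, nine melanogaster-group
  species) — a synthetic calibration stand-in with the published group
  structure and subgenus split age, used by the simulator and tests;
* the species -> taxonomic-group table driving OU regime painting;
* the published direction-concordance comparison tables: per-experiment
  (same, opposite) direction counts for eleven lifespan-intervention
  microarray experiments, and the curated longevity-gene effect table
  (18 genes with correlation signs and pro-/anti-longevity annotations).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .phylo import Phylogeny, RegimeMap

__all__ = [
    "fixture_tree",
    "species_groups",
    "regime_map",
    "microarray_direction_counts",
    "curated_longevity_effects",
]


def _data(name: str):
    return resources.files("longsig.data").joinpath(name)


def fixture_tree() -> Phylogeny:
    """The 14-taxon ultrametric fixture tree (depth 56 My)."""
    return Phylogeny.from_newick(_data("drosophila14.nwk").read_text())


def species_groups() -> pd.DataFrame:
    """Species table with ``subgenus`` and ``group`` columns."""
    with resources.as_file(_data("species_groups.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def regime_map(tree: Phylogeny | None = None, k: int = 2) -> RegimeMap:
    """Taxonomic regime painting for the fixture species.

    k=2: subgenus *Drosophila* vs *Sophophora*.
    k=3: subgenus *Drosophila* / melanogaster group / other *Sophophora*.
    """
    if tree is None:
        tree = fixture_tree()
    df = species_groups()
    if k == 1:
        mapping = {s: "all" for s in df["species"]}
    elif k == 2:
        mapping = dict(zip(df["species"], df["subgenus"]))
    elif k == 3:
        mapping = {
            s: (sub if sub == "Drosophila"
                else ("melanogaster" if grp == "melanogaster" else "other_sophophora"))
            for s, sub, grp in zip(df["species"], df["subgenus"], df["group"])
        }
    else:
        raise ValueError("k must be 1, 2 or 3")
    root_group = mapping["Dvir"]  # outgroup side of the root
    return RegimeMap(tree, mapping, root_group=root_group)


def microarray_direction_counts() -> pd.DataFrame:
    """Published (same, opposite) direction counts for the 11
    lifespan-intervention microarray comparisons."""
    with resources.as_file(_data("microarray_concordance.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def curated_longevity_effects() -> pd.DataFrame:
    """Curated longevity-gene table: correlation sign and pro-/anti-longevity
    annotation for the 18 database-matched signature genes."""
    with resources.as_file(_data("curated_longevity_effects.tsv")) as p:
        return pd.read_csv(p, sep="\t")
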