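"""Join bio-transparency traits onto an existing phylogeny.

The tree is taken as *given* (this package infers nothing); the job is a
careful label join: tip names are matched to trait-table species exactly,
after optional alias mapping and underscore/space normalization.  Fuzzy
matching is deliberately absent -- a silent mis-join onto the wrong
species is worse than an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import pandas as pd

from .errors import TreeJoinError

logger = logging.getLogger(__name__)

__all__ = ["annotate_tree"]


def _normalize(name: str) -> str:
    return " ".join(name.replace("_", " ").split()).strip().lower()


def annotate_tree(tree_path: str | Path,
                  traits: pd.DataFrame,
                  out_path: str | Path,
                  name_map: dict[str, str] | None = None) -> tuple[Path, Path]:
    """Attach per-species bio-transparency to tree tips and write NEXUS.

    Parameters
    ----------
    tree_path : path
        Newick tree whose tip labels are (aliases of) species names.
    traits : DataFrame
        Must contain a ``species`` column and at least ``mean_bt_pct``;
        ``sd_bt_pct`` / ``n_individuals`` are carried along when present.
    out_path : path
        NEXUS output; a ``<out>.tips.csv`` tip-to-trait table is written
        next to it.
    name_map : dict, optional
        Tip-label -> trait-species aliases, applied before normalization.

    Unmatched tips are logged and kept in the tree un-annotated; zero
    matches raises :class:`TreeJoinError`.
    """
    tree_path = Path(tree_path)
    out_path = Path(out_path)
    name_map = name_map or {}
    tree = dendropy.Tree.get(path=str(tree_path), schema="newick")

    lookup = {_normalize(str(row["species"])): row
              for _, row in traits.iterrows()}
    trait_cols = [c for c in ("mean_bt_pct", "sd_bt_pct", "n_individuals")
                  if c in traits.columns]

    rows = []
    n_matched = 0
    for taxon in tree.taxon_namespace:
        label = taxon.label or ""
        target = name_map.get(label, name_map.get(label.replace(" ", "_"), label))
        row = lookup.get(_normalize(target))
        record = {"tip_label": label, "matched_species": None}
        if row is not None:
            n_matched += 1
            record["matched_species"] = row["species"]
            for col in trait_cols:
                taxon.annotations.add_new(col, float(row[col]))
                record[col] = float(row[col])
        else:
            logger.warning("tree tip %r matched no trait row; kept un-annotated",
                           label)
        rows.append(record)

    if n_matched == 0:
        raise TreeJoinError(
            "no tree tip matched any trait species. "
            f"tips: {[t.label for t in tree.taxon_namespace]}; "
            f"trait species: {list(traits['species'])}. "
            "Provide a name_map with aliases."
        )

    out_path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(out_path), schema="nexus", suppress_annotations=False)
    csv_path = out_path.with_suffix(out_path.suffix + ".tips.csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    logger.info("annotated %d/%d tips", n_matched, len(tree.taxon_namespace))
    return out_path, csv_path
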