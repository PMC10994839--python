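"""Readers and writers for plate tables, panels, trees, results and config.

All tabular I/O is plain delimited text (comma by default, tab accepted); the
long plate format has one row per well per time point with columns
``culture, well, chemicals, replicate, time_h, od`` where ``chemicals`` is a
semicolon-joined list of panel names (empty for the no-chemical control).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
import yaml

from .panel import ChemicalPanel, MixtureDesign, PanelError

log = logging.getLogger(__name__)

PLATE_COLUMNS = ("culture", "well", "chemicals", "replicate", "time_h", "od")


class PlateFormatError(ValueError):
    """The file does not have the documented long plate format."""


class PlateValidationError(ValueError):
    """The table parses but violates a plate invariant."""


def _sep_for(path: str | Path, sep: str | None) -> str | None:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def parse_chemicals(field: object, panel: ChemicalPanel) -> MixtureDesign:
    """Parse a semicolon-joined chemicals field into a design.

    Empty/NaN fields encode the control. Unknown names raise
    :class:`PlateValidationError` naming the offender.
    """
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return MixtureDesign.control(panel)
    text = str(field).strip()
    if not text:
        return MixtureDesign.control(panel)
    names = [t.strip() for t in text.split(";") if t.strip()]
    try:
        return MixtureDesign.from_names(names, panel)
    except PanelError as e:
        raise PlateValidationError(str(e)) from None


def read_plate_table(
    path: str | Path,
    panel: ChemicalPanel,
    sep: str | None = None,
    exclude_wells: Iterable[str] = (),
) -> pd.DataFrame:
    """Read and validate a long-format plate table.

    Returns a DataFrame with the plate columns plus a ``mixture`` column of
    :class:`MixtureDesign` objects. ``exclude_wells`` removes wells by id
    (the explicit contamination-exclusion list); removals are logged.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate table is missing columns {missing}")
    df = df.copy()
    df["chemicals"] = df["chemicals"].fillna("")
    df["mixture"] = df["chemicals"].map(lambda s: parse_chemicals(s, panel))
    excluded = set(exclude_wells)
    if excluded:
        n0 = df["well"].nunique()
        df = df[~df["well"].isin(excluded)]
        log.info("excluded %d of %d wells by exclusion list", n0 - df["well"].nunique(), n0)
    validate_plate_table(df)
    return df.reset_index(drop=True)


def validate_plate_table(df: pd.DataFrame) -> None:
    """Check plate invariants: unique (well, time), one condition per well,
    strictly increasing time grid per well, non-negative readings."""
    if df.duplicated(subset=["well", "time_h"]).any():
        bad = df[df.duplicated(subset=["well", "time_h"])]["well"].unique()[:5]
        raise PlateValidationError(f"duplicate (well, time_h) rows, e.g. wells {list(bad)}")
    meta = df.groupby("well")[["culture", "chemicals", "replicate"]].nunique()
    multi = meta[(meta > 1).any(axis=1)]
    if len(multi):
        raise PlateValidationError(
            f"wells mapped to more than one (culture, mixture, replicate): {list(multi.index[:5])}"
        )
    for well, grp in df.groupby("well"):
        t = grp["time_h"].to_numpy(float)
        if not np.all(np.diff(t) > 0):
            order = np.argsort(t, kind="stable")
            if np.all(np.diff(t[order]) > 0):
                raise PlateValidationError(
                    f"well {well!r}: time grid not sorted (rows must be time-ordered per well)"
                )
            raise PlateValidationError(f"well {well!r}: non-monotone time grid")
    if (df["od"].to_numpy(float) < 0).any():
        raise PlateValidationError("negative OD readings present")
    if (df["time_h"].to_numpy(float) < 0).any():
        raise PlateValidationError("negative time points present")


def write_plate_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    out = df[list(PLATE_COLUMNS)]
    out.to_csv(path, sep=_sep_for(path, sep) or ",", index=False)


def read_panel(path: str | Path) -> ChemicalPanel:
    """Read a panel file: one chemical name per line (or a 'chemical' CSV
    column); file order fixes the canonical index order."""
    text = Path(path).read_text().strip()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines and ("," in lines[0] or lines[0].lower() == "chemical"):
        df = pd.read_csv(path)
        col = "chemical" if "chemical" in df.columns else df.columns[0]
        names = [str(x) for x in df[col]]
    else:
        names = lines
    return ChemicalPanel(tuple(names))


def write_panel(panel: ChemicalPanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.names) + "\n")


def read_newick(
    path: str | Path,
    min_branch_length: float = 1e-8,
    require_tips: Iterable[str] | None = None,
) -> dendropy.Tree:
    """Read a rooted newick tree with unique tip labels.

    Zero or missing branch lengths are replaced by ``min_branch_length``
    (logged); duplicate or unlabelled tips raise. If ``require_tips`` is
    given, every listed label must be present.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate tip labels in tree: {e}") from None
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unlabelled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    n_fixed = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = min_branch_length
            n_fixed += 1
    if n_fixed:
        log.info("replaced %d zero/missing branch lengths with %g", n_fixed, min_branch_length)
    if require_tips is not None:
        missing = sorted(set(require_tips) - set(labels))
        extra = sorted(set(labels) - set(require_tips))
        if missing or extra:
            raise ValueError(
                f"tree/table tip mismatch: missing from tree {missing}, unmatched in tree {extra}"
            )
    return tree


def load_config(path: str | Path) -> dict:
    """Load a YAML (or key: value) config file into a flat dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping of settings")
    return cfg


def write_results(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    df.to_csv(path, sep=_sep_for(path, sep) or ",", index=False)
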