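"""PSM-level FDR filtering and secretome fraction set algebra.

The mass-spectrometry side of the prioritization funnel: peptide-spectrum
matches (PSMs) are filtered by the target-decoy method at a 1% FDR on both
the peptide and the protein level (peptides shorter than 7 residues are
discarded first), and the surviving protein identifications from the
bioactive secretome fractions are combined by set algebra — union of the
bioactive fractions, subtraction of the serum background and of the
inactive control proteome, and intersection across experiments — to yield
the candidate secretome protein list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSM_COLUMNS = ["peptide", "protein", "length", "score", "is_decoy"]


@dataclass
class FractionProteome:
    """Protein identifications from one secretome fraction.

    activity is one of ``bioactive`` (supports plasma-cell survival in
    culture), ``inactive`` (control fraction with little or no survival
    activity), or ``background`` (serum-only, e.g. FBS).
    """

    fraction_id: str
    activity: str
    proteins: set[str]

    def __post_init__(self) -> None:
        if self.activity not in {"bioactive", "inactive", "background"}:
            raise ValueError(
                f"activity must be bioactive/inactive/background, got {self.activity!r}"
            )
        self.proteins = {p for p in (str(x).upper() for x in self.proteins) if p}


@dataclass
class ProteinSetReport:
    """Provenance-tracked output of the fraction set-algebra funnel."""

    union_active: set[str]
    differential: set[str]
    intersection: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "union_active": sorted(self.union_active),
            "differential": sorted(self.differential),
            "intersection": sorted(self.intersection),
            "provenance": {k: sorted(v) for k, v in self.provenance.items()},
        }


def _as_psm_frame(psms) -> pd.DataFrame:
    df = pd.DataFrame(psms)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing columns {missing}")
    return df


def _target_decoy_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Concatenated-search q-values: running minimum over score thresholds
    of (#decoys >= s) / (#targets >= s).

    Decoys sort ahead of targets at tied scores (conservative). Returns one
    q-value per input row, in input order.
    """
    n = len(scores)
    # sort descending by score; decoys first within ties
    order = np.lexsort((~is_decoy, -scores))
    d = is_decoy[order].astype(np.int64)
    n_decoy = np.cumsum(d)
    n_target = np.cumsum(1 - d)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1), np.inf)
    # q at rank i = best FDR achievable by any threshold at or below this score
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


def psm_qvalues(psms, min_length: int = 7, plus_one: bool = False) -> pd.DataFrame:
    """Peptide-level target-decoy q-values after the length filter.

    Returns the filtered table with a ``q`` column; useful for inspecting
    the estimator before protein roll-up.
    """
    df = _as_psm_frame(psms)
    if not bool(df["is_decoy"].any()):
        raise ValueError("q-value estimation requires at least one decoy")
    df = df[df["length"] >= min_length].copy()
    if len(df) == 0:
        df["q"] = pd.Series(dtype=float)
        return df
    fn = _target_decoy_qvalues_plus_one if plus_one else _target_decoy_qvalues
    df["q"] = fn(df["score"].to_numpy(dtype=float), df["is_decoy"].to_numpy(bool))
    return df


def filter_psms(
    psms,
    fdr_threshold: float = 0.01,
    min_length: int = 7,
    plus_one: bool = False,
) -> set[str]:
    """Target-decoy filter of a PSM table; returns the passing target proteins.

    Peptides shorter than ``min_length`` residues are removed, peptide
    q-values are estimated from the decoy population and thresholded, the
    surviving identifications are aggregated to proteins by their best
    peptide score, and the same target-decoy q-value procedure is repeated
    at the protein level with the same threshold.

    Parameters
    ----------
    psms : DataFrame-like with columns peptide, protein, length, score, is_decoy
    fdr_threshold : acceptance level for both peptide and protein q-values
    min_length : minimum peptide length in amino-acid residues
    plus_one : if True use the conservative (#decoys + 1)/#targets estimator
    """
    df = _as_psm_frame(psms)
    if len(df) == 0:
        warnings.warn("empty PSM table; returning empty protein set")
        return set()
    if not bool(df["is_decoy"].any()):
        raise ValueError(
            "PSM table contains no decoys; target-decoy FDR estimation "
            "requires a decoy population"
        )
    df = df[df["length"] >= min_length]
    if len(df) == 0 or not bool((~df["is_decoy"]).any()):
        return set()

    scores = df["score"].to_numpy(dtype=float)
    decoy = df["is_decoy"].to_numpy(dtype=bool)
    q = _target_decoy_qvalues(scores, decoy)
    if plus_one:
        q = _target_decoy_qvalues_plus_one(scores, decoy)
    keep = q <= fdr_threshold
    confident = df[keep]
    if len(confident) == 0 or not bool((~confident["is_decoy"]).any()):
        return set()

    # protein level: best peptide score per protein, targets and decoys alike
    best = (
        confident.groupby(["protein", "is_decoy"], sort=False)["score"]
        .max()
        .reset_index()
    )
    if not bool(best["is_decoy"].any()):
        # all decoy peptides were filtered out: every remaining protein-level
        # threshold has an estimated FDR of 0
        return set(best.loc[~best["is_decoy"], "protein"])
    pq = _target_decoy_qvalues(
        best["score"].to_numpy(dtype=float), best["is_decoy"].to_numpy(dtype=bool)
    )
    if plus_one:
        pq = _target_decoy_qvalues_plus_one(
            best["score"].to_numpy(dtype=float), best["is_decoy"].to_numpy(dtype=bool)
        )
    ok = best[(pq <= fdr_threshold) & (~best["is_decoy"])]
    return set(ok["protein"])


def _target_decoy_qvalues_plus_one(scores, is_decoy) -> np.ndarray:
    """(#decoys + 1)/#targets variant of the q-value estimator."""
    n = len(scores)
    order = np.lexsort((~is_decoy, -scores))
    d = is_decoy[order].astype(np.int64)
    n_decoy = np.cumsum(d) + 1
    n_target = np.cumsum(1 - d)
    with np.errstate(divide="ignore"):
        fdr = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1), np.inf)
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


def normalize_identifiers(
    raw_ids: Iterable[str],
    mapping: Mapping[str, str] | None = None,
    isoform_delimiter: str = "-",
) -> set[str]:
    """Map raw protein identifiers to upper-case gene symbols.

    Applies ``mapping`` when a raw id (case-insensitively) matches a key;
    otherwise upper-cases the id and strips a numeric isoform suffix after
    ``isoform_delimiter`` (``YWHAZ-2`` → ``YWHAZ``). Unmapped ids are passed
    through with a logged warning count.
    """
    lut = {str(k).upper(): str(v).upper() for k, v in (mapping or {}).items()}
    out: set[str] = set()
    n_unmapped = 0
    for raw in raw_ids:
        s = str(raw).strip().upper()
        if not s:
            continue
        if s in lut:
            out.add(lut[s])
            continue
        if mapping is not None:
            n_unmapped += 1
        if isoform_delimiter and isoform_delimiter in s:
            head, _, tail = s.rpartition(isoform_delimiter)
            if head and tail.isdigit():
                s = head
        out.add(s)
    if n_unmapped:
        logger.warning("%d identifiers had no mapping entry; passed through", n_unmapped)
    return out


def subtract_background(proteome: set[str], background: set[str]) -> set[str]:
    """Remove background (e.g. FBS serum) identifications: set difference."""
    return set(proteome) - set(background)


def union_active(fractions: Sequence[FractionProteome]) -> set[str]:
    """Union of the bioactive fractions' protein sets."""
    if not fractions:
        raise ValueError("no fractions given")
    for f in fractions:
        if f.activity != "bioactive":
            raise ValueError(
                f"union_active expects bioactive fractions; {f.fraction_id!r} "
                f"has activity {f.activity!r}"
            )
    out: set[str] = set()
    for f in fractions:
        out |= f.proteins
    return out


def differential_proteome(secretome: set[str], control: set[str]) -> set[str]:
    """Proteins of the active secretome absent from the control proteome."""
    return set(secretome) - set(control)


def intersect_experiments(set_a: set[str], set_b: set[str]) -> ProteinSetReport:
    """Overlap of two independent experiments' protein sets, with provenance."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    prov = {p: (["experiment_a"] if p in a else []) + (["experiment_b"] if p in b else [])
            for p in a | b}
    return ProteinSetReport(union_active=a | b, differential=a - b,
                            intersection=inter, provenance=prov)


def run_funnel(fractions: Sequence[FractionProteome]) -> ProteinSetReport:
    """The full fraction funnel: union of bioactive fractions, background
    subtraction, subtraction of the inactive control proteome, and the
    intersection of the per-fraction cleaned sets across bioactive fractions.

    Returns a report whose ``intersection`` is the candidate secretome
    protein list the downstream network expansion consumes.
    """
    actives = [f for f in fractions if f.activity == "bioactive"]
    inactives = [f for f in fractions if f.activity == "inactive"]
    backgrounds = [f for f in fractions if f.activity == "background"]
    if not actives:
        raise ValueError("funnel requires at least one bioactive fraction")
    background = set().union(*(f.proteins for f in backgrounds)) if backgrounds else set()
    inactive = set().union(*(f.proteins for f in inactives)) if inactives else set()

    union_act = union_active(actives)
    secretome = subtract_background(union_act, background)
    differential = differential_proteome(secretome, inactive)

    cleaned = [differential_proteome(subtract_background(f.proteins, background), inactive)
               for f in actives]
    intersection = set(cleaned[0])
    for c in cleaned[1:]:
        intersection &= c

    provenance: dict[str, list[str]] = {}
    for f, c in zip(actives, cleaned):
        for p in c:
            provenance.setdefault(p, []).append(f.fraction_id)
    logger.info(
        "funnel: union_active=%d, after background=%d, differential=%d, intersection=%d",
        len(union_act), len(secretome), len(differential), len(intersection),
    )
    return ProteinSetReport(
        union_active=union_act,
        differential=differential,
        intersection=intersection,
        provenance=provenance,
    )
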