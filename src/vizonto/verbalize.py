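"""Axiom verbalization and rater-agreement statistics.

Logical axioms are rendered as English review sentences from fixed,
deterministic templates (lower-case entity labels):

* subclass — "every ellipse is a shape"
* exact cardinality — "every decagon is something that has exactly 10 points"
* max cardinality — "every decagon is something that has at most 10 points"
* existential restriction — "every rosettes is something that has shape some circle"
* data-property range — "every stroke-width value is an integer"

Reviewers rate each sentence Y (agree), N (disagree) or X (not sure);
X counts as a negative when recoded (an unclear axiom is not a correct
axiom), so Y -> 1 and both N and X -> 0.  From a rating matrix the module
computes per-rater agreement proportions, their unweighted mean, the mean
pairwise percent agreement across rater pairs (on recoded values by
default; raw {Y,N,X} comparison is available), and the list of contested
statements (those with at least a threshold number of recoded zeros).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .owl_io import OntologyModel

_CAMEL_SPLIT = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")

SUPPORTED_AXIOM_KINDS = (
    "SubClassOf",
    "SubClassOfRestriction",  # exact/max/min cardinality and existential
    "Range",  # data-property range
)


@dataclass(frozen=True)
class Statement:
    axiom: tuple
    sentence: str
    template: str


def _label(name: str, model: Optional[OntologyModel]) -> str:
    """Human label for an entity fragment, lower-cased for templates."""
    if model is not None:
        decl = model.classes.get(name)
        if decl is not None:
            return decl.pref_label.lower()
        prop = model.properties.get(name)
        if prop is not None and prop.pref_label:
            return prop.pref_label.lower()
    return _CAMEL_SPLIT.sub(" ", name).replace("-", " ").lower()


def _plural(noun: str, n: int) -> str:
    if n == 1:
        return noun
    if noun.endswith(("s", "x", "ch", "sh")):
        return noun + "es"
    return noun + "s"


def _prop_phrase(prop: str, model: Optional[OntologyModel]) -> str:
    return _label(prop, model)


def verbalize(axiom: tuple, model: Optional[OntologyModel] = None) -> Statement:
    """Render one axiom tuple (as produced by ``OntologyModel.axioms()``)
    as an English review sentence.

    >>> verbalize(("SubClassOf", "Ellipse", "Shape")).sentence
    'every ellipse is a shape'
    """
    kind = axiom[0]
    if kind == "SubClassOf":
        _, sub, sup = axiom
        return Statement(axiom, f"every {_label(sub, model)} is a {_label(sup, model)}", "subclass")
    if kind == "SubClassOfRestriction":
        _, cls, prop, rkind, n, filler = axiom
        cls_l = _label(cls, model)
        if rkind in ("exactly", "max", "min"):
            word = {"exactly": "exactly", "max": "at most", "min": "at least"}[rkind]
            noun = _plural(_label(filler, model) if filler else _prop_phrase(prop, model), n)
            return Statement(
                axiom,
                f"every {cls_l} is something that has {word} {n} {noun}",
                f"{rkind}-cardinality",
            )
        if rkind == "some":
            return Statement(
                axiom,
                f"every {cls_l} is something that {_prop_phrase(prop, model)} some {_label(filler, model)}",
                "existential",
            )
        raise ValidationError(f"unsupported restriction kind {rkind!r}")
    if kind == "Range":
        _, prop, rng = axiom
        if not str(rng).startswith("xsd:"):
            raise ValidationError("only data-property ranges are verbalized")
        return Statement(
            axiom,
            f"every {_prop_phrase(prop, model)} value is an {rng.split(':')[1]}",
            "data-range",
        )
    raise ValidationError(f"unsupported axiom kind {kind!r}; supported: {SUPPORTED_AXIOM_KINDS}")


def verbalize_model(model: OntologyModel) -> list[Statement]:
    """All verbalizable axioms of a model, in deterministic axiom order."""
    out = []
    for ax in model.axioms():
        if ax[0] == "SubClassOf":
            out.append(verbalize(ax, model))
        elif ax[0] == "SubClassOfRestriction":
            out.append(verbalize(ax, model))
        elif ax[0] == "Range" and str(ax[2]).startswith("xsd:"):
            out.append(verbalize(ax, model))
    return out


def review_sheet(statements: list[Statement], raters: int = 3) -> pd.DataFrame:
    """Empty review sheet: statement id, sentence, one column per rater."""
    df = pd.DataFrame(
        {
            "id": range(1, len(statements) + 1),
            "sentence": [s.sentence for s in statements],
        }
    )
    for i in range(1, raters + 1):
        df[f"rater{i}"] = ""
    return df


# ---------------------------------------------------------------------------
# rating matrices

VALID_RATINGS = ("Y", "N", "X")


def recode(cell: str) -> int:
    """Numeric recoding of one rating: Y -> 1, N -> 0, X -> 0.

    X (not sure) counts as a negative: an unclear axiom is not accepted.
    """
    if cell == "Y":
        return 1
    if cell in ("N", "X"):
        return 0
    raise ValidationError(f"invalid rating {cell!r}; expected one of {VALID_RATINGS}")


def _as_matrix(m: Union[pd.DataFrame, np.ndarray, list]) -> pd.DataFrame:
    df = pd.DataFrame(m)
    if df.size == 0:
        raise ValidationError("empty rating matrix")
    if df.isna().any().any():
        raise ValidationError("rating matrix has missing cells")
    bad = set(np.unique(df.values)) - set(VALID_RATINGS)
    if bad:
        raise ValidationError(f"invalid ratings {sorted(bad)}; expected {VALID_RATINGS}")
    return df


def recode_matrix(m: Union[pd.DataFrame, np.ndarray, list]) -> pd.DataFrame:
    df = _as_matrix(m)
    return df.map(recode)


def agreement_stats(
    m: Union[pd.DataFrame, np.ndarray, list],
    pairwise_on: str = "recoded",
) -> dict:
    """Agreement statistics for a statements x raters matrix of Y/N/X.

    Returns ``per_rater`` (proportion of recoded 1s per rater),
    ``mean_agreement`` (their unweighted mean) and
    ``pairwise_percent_agreement`` (mean over rater pairs of the fraction
    of statements on which the pair agrees; compared on recoded values by
    default, or on the raw symbols with ``pairwise_on="raw"``).
    """
    df = _as_matrix(m)
    if df.shape[1] < 2:
        raise ValidationError(f"need at least 2 raters, got {df.shape[1]}")
    if pairwise_on not in ("recoded", "raw"):
        raise ValidationError(f"pairwise_on must be 'recoded' or 'raw', got {pairwise_on!r}")
    rec = df.map(recode)
    per_rater = {col: float(rec[col].mean()) for col in rec.columns}
    mean_agreement = float(np.mean(list(per_rater.values())))
    basis = rec if pairwise_on == "recoded" else df
    pair_values = [
        float((basis[a] == basis[b]).mean())
        for a, b in itertools.combinations(basis.columns, 2)
    ]
    return {
        "per_rater": per_rater,
        "mean_agreement": mean_agreement,
        "pairwise_percent_agreement": float(np.mean(pair_values)),
    }


def contested_statements(
    m: Union[pd.DataFrame, np.ndarray, list], threshold: int = 2
) -> list:
    """Row labels of statements with at least ``threshold`` recoded zeros
    (N or X ratings), in input order."""
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    rec = recode_matrix(m)
    zeros = (rec == 0).sum(axis=1)
    return [idx for idx in rec.index if zeros[idx] >= threshold]


def disagreement_percentage(disagreed: int, total: int, digits: int = 1) -> float:
    """Share of reviewed definitions a rater disagreed with, as a percent
    (half-to-even display rounding): 12 of 48 -> 25.0, 5 of 48 -> 10.4."""
    from .metrics import round_half_even

    if total <= 0 or disagreed < 0 or disagreed > total:
        raise ValidationError(f"invalid counts: {disagreed}/{total}")
    return round_half_even(100.0 * disagreed / total, digits)


def load_ratings(path: Union[str, Path]) -> pd.DataFrame:
    """Load a rating matrix CSV (first column = statement id, remaining
    columns = raters)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    return _as_matrix(df)
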