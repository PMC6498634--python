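"""Risk chart: model coefficients → profile risk percentages with
interquartile color bands.

A *profile* is a detected community (all of its member predictors present,
everything else at reference) combined with an age group and a nationality;
the risk score is the sum of the intercept and the active coefficients, and
the risk percentage is its inverse logit, ``100 · e^s / (1 + e^s)``. Cells
are banded Q1–Q4 by the quartiles of the grid's own percentage distribution
(green = lowest risk band, red = highest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph_analysis import CommunityPartition
from .model import AGE_DUMMIES, LogisticModel

__all__ = [
    "RiskProfile",
    "RiskChart",
    "risk_score",
    "risk_percent",
    "community_predictor_map",
    "build_risk_chart",
]

AGE_GROUPS = ("15-24", "25-34", "35-54", "55-70")
NATIONALITIES = ("foreign", "italian")
BAND_COLORS = {"Q1": "#2ca02c", "Q2": "#bcbd22", "Q3": "#ff7f0e", "Q4": "#d62728"}


@dataclass
class RiskProfile:
    """Active predictors plus demographics for one chart cell."""

    active: tuple[str, ...]            # predictor terms set to present
    age_group: str = "15-24"           # reference: 15-24
    nationality: str = "foreign"       # reference: foreign
    residence: str = "metro_rome"      # chart default: inside Rome

    def terms(self) -> list[str]:
        terms = list(self.active)
        for dummy, level in AGE_DUMMIES.items():
            if self.age_group == level:
                terms.append(dummy)
        if self.nationality == "italian":
            terms.append("nationality_italian")
        elif self.nationality == "missing":
            terms.append("nationality_missing")
        if self.residence == "metro_rome":
            terms.append("residence_metro")
        return terms


def risk_score(model: LogisticModel, profile) -> float:
    """Sum of the intercept and the coefficients of the active terms.

    ``profile`` may be a :class:`RiskProfile` or an iterable of term names.
    Unknown terms raise ``KeyError``.
    """
    terms = profile.terms() if isinstance(profile, RiskProfile) else list(profile)
    score = model.intercept
    for term in terms:
        score += model.coefficient(term)
    return float(score)


def risk_percent(score: float) -> float:
    """Risk percentage 100 · e^s / (1 + e^s); strictly increasing in s."""
    return float(100.0 * expit(score))


def community_predictor_map(partition: CommunityPartition,
                            model: LogisticModel) -> dict[str, list[str]]:
    """Community label → the member categories that are model predictors.

    Emitted as a plain dict so users can edit the mapping before charting.
    Labels are 'community_<k>' in ascending label order.
    """
    model_terms = set(model.terms)
    out: dict[str, list[str]] = {}
    for label, members in sorted(
        ((lab, members) for lab, members in _groups(partition).items())
    ):
        preds = sorted(m for m in members if m in model_terms)
        out[f"community_{label}"] = preds
    return out


def _groups(partition: CommunityPartition) -> dict[int, set[str]]:
    groups: dict[int, set[str]] = {}
    for node, lab in partition.assignment.items():
        groups.setdefault(lab, set()).add(node)
    return groups


@dataclass
class RiskChart:
    """Grid of risk percentages over community × age × nationality."""

    grid: pd.DataFrame                  # long: community, age_group, nationality,
                                        # risk_pct, band, demographics_only
    quartiles: tuple[float, float, float]
    residence: str
    mapping: dict[str, list[str]] = field(default_factory=dict)

    def pivot(self) -> pd.DataFrame:
        return self.grid.pivot_table(index="community",
                                     columns=["nationality", "age_group"],
                                     values="risk_pct")

    def write(self, outdir) -> None:
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.grid.to_csv(out / "risk_chart.csv", index=False)
        (out / "risk_chart.json").write_text(json.dumps({
            "quartiles": list(self.quartiles),
            "residence": self.residence,
            "communities": self.mapping,
            "cells": self.grid.to_dict(orient="records"),
        }, indent=1))
        (out / "risk_chart.html").write_text(self.to_html())

    def to_html(self) -> str:
        rows = []
        piv = self.pivot()
        bands = self.grid.set_index(["community", "nationality", "age_group"])["band"]
        header = "".join(
            f"<th>{nat} {age}</th>" for nat, age in piv.columns
        )
        for comm in piv.index:
            cells = "".join(
                f'<td style="background:{BAND_COLORS[bands.loc[(comm, nat, age)]]}">'
                f"{piv.loc[comm, (nat, age)]:.2f}</td>"
                for nat, age in piv.columns
            )
            rows.append(f"<tr><th>{comm}</th>{cells}</tr>")
        return ("<table><tr><th>community (risk %)</th>" + header + "</tr>"
                + "".join(rows) + "</table>")


def build_risk_chart(model: LogisticModel,
                     communities: CommunityPartition | dict[str, list[str]],
                     age_groups=AGE_GROUPS, nationalities=NATIONALITIES,
                     residence: str = "metro_rome") -> RiskChart:
    """Risk percentages for every (community, age group, nationality) cell.

    ``communities`` may be a detected partition (mapped to predictors via
    :func:`community_predictor_map`) or an explicit label → predictor-list
    mapping. Communities containing no model predictor produce cells
    computed from demographics alone, flagged ``demographics_only``.
    Bands partition the grid by its own quartiles; when the quartiles are
    degenerate every cell falls into the lowest band.
    """
    if isinstance(communities, CommunityPartition):
        mapping = community_predictor_map(communities, model)
    else:
        mapping = {k: list(v) for k, v in communities.items()}

    rows = []
    for comm, preds in mapping.items():
        for nat in nationalities:
            for age in age_groups:
                prof = RiskProfile(tuple(preds), age_group=age,
                                   nationality=nat, residence=residence)
                pct = risk_percent(risk_score(model, prof))
                rows.append({
                    "community": comm,
                    "age_group": age,
                    "nationality": nat,
                    "risk_pct": pct,
                    "demographics_only": len(preds) == 0,
                })
    grid = pd.DataFrame(rows)
    q1, q2, q3 = np.percentile(grid["risk_pct"], [25, 50, 75])

    def band(x: float) -> str:
        if x <= q1:
            return "Q1"
        if x <= q2:
            return "Q2"
        if x <= q3:
            return "Q3"
        return "Q4"

    grid["band"] = grid["risk_pct"].map(band)
    return RiskChart(grid=grid, quartiles=(float(q1), float(q2), float(q3)),
                     residence=residence, mapping=mapping)
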