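"""Analytical greenness metrics: Eco-scale penalty points and AGREE.

The Analytical Eco-scale starts from 100 and subtracts penalty points for
reagents (pictogram count × signal-word multiplier × amount bracket),
instrument energy, occupational hazard and waste; a score above 75 is an
"excellent green analysis", above 50 "acceptable", otherwise "inadequate".
The AGREE-style aggregator combines twelve principle scores in [0, 1] by a
weighted arithmetic mean. The rule tables ship as an editable YAML data file;
item lists for the spectrophotometric-chemometric procedure (methanol
solvent) and the water-based reference method are provided as canonical
examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PenaltyItem",
    "EcoScaleReport",
    "AGREEReport",
    "load_rules",
    "eco_scale",
    "agree_score",
    "proposed_method_items",
    "reference_method_items",
    "load_agree_fixture",
]

CATEGORIES = ("reagent", "instrument", "occupational_hazard", "waste")


def load_rules(path=None) -> dict:
    """Eco-scale rule tables (signal words, amount/energy/waste brackets)."""
    if path is None:
        src = resources.files("specresolve.data").joinpath("ecoscale_rules.yaml")
        with resources.as_file(src) as p:
            return yaml.safe_load(Path(p).read_text())
    return yaml.safe_load(Path(path).read_text())


@dataclass
class PenaltyItem:
    """One scored entry of the Eco-scale penalty table.

    Reagents are scored ``pictogram_count × signal_word × amount_bracket``;
    the other categories are direct bracket lookups via ``subcategory``.
    ``points`` may be given explicitly to override the rule tables.
    """

    name: str
    category: str
    pictogram_count: int = 0
    signal_word: str = "none"
    amount_bracket: str | None = None
    subcategory: str | None = None
    points: int | None = None

    def compute_points(self, rules: dict) -> int:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.points is not None:
            if self.points < 0:
                raise ValueError("penalty points must be >= 0")
            return int(self.points)
        if self.category == "reagent":
            if self.pictogram_count < 0:
                raise ValueError("pictogram_count must be >= 0")
            sw = rules["signal_word"][self.signal_word]
            amount = 1 if self.amount_bracket is None else rules["reagent_amount"][self.amount_bracket]
            return int(self.pictogram_count * sw * amount)
        table_key = {
            "instrument": "instrument_energy",
            "occupational_hazard": "occupational_hazard",
            "waste": "waste",
        }[self.category]
        if self.subcategory is None:
            raise ValueError(f"{self.category} item needs a subcategory")
        return int(rules[table_key][self.subcategory])


@dataclass
class EcoScaleReport:
    items: list
    item_points: list
    total_pp: int
    score: int
    verdict: str

    def to_dict(self) -> dict:
        return {
            "items": [
                {"name": it.name, "category": it.category, "points": pts}
                for it, pts in zip(self.items, self.item_points)
            ],
            "total_penalty_points": self.total_pp,
            "score": self.score,
            "verdict": self.verdict,
        }


@dataclass
class AGREEReport:
    principle_scores: np.ndarray
    weights: np.ndarray
    overall: float

    def to_dict(self) -> dict:
        return {
            "principle_scores": [float(s) for s in self.principle_scores],
            "weights": [float(w) for w in self.weights],
            "overall": float(self.overall),
        }


def eco_scale(items, rules: dict | None = None) -> EcoScaleReport:
    """Score a procedure: 100 minus the summed penalty points of its items."""
    rules = rules or load_rules()
    item_points = [it.compute_points(rules) for it in items]
    total = int(sum(item_points))
    score = max(0, 100 - total)
    thresholds = rules["verdict_thresholds"]
    if score > thresholds["excellent"]:
        verdict = "excellent"
    elif score > thresholds["acceptable"]:
        verdict = "acceptable"
    else:
        verdict = "inadequate"
    return EcoScaleReport(list(items), item_points, total, score, verdict)


def agree_score(principle_scores, weights=None) -> AGREEReport:
    """Weighted arithmetic mean of the twelve AGREE principle scores."""
    s = np.asarray(principle_scores, dtype=float)
    if s.shape != (12,):
        raise ValueError("AGREE expects exactly 12 principle scores")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("principle scores must lie in [0, 1]")
    w = np.ones(12) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (12,) or np.any(w <= 0):
        raise ValueError("weights must be 12 positive values")
    overall = float(np.sum(w * s) / np.sum(w))
    return AGREEReport(s, w, overall)


def proposed_method_items() -> list:
    """Penalty items of the direct UV-Vis chemometric procedure.

    Methanol is the only reagent (3 GHS pictograms, signal word danger,
    10–100 mL consumed per run); the spectrophotometer draws under 0.1 kWh per
    sample, the process is hermetic, and 1–10 mL of waste per sample goes
    uncollected.
    """
    return [
        PenaltyItem("methanol", "reagent", pictogram_count=3,
                    signal_word="danger", amount_bracket="10-100 mL"),
        PenaltyItem("UV-Vis spectrophotometer", "instrument", subcategory="<=0.1 kWh"),
        PenaltyItem("hermetic procedure", "occupational_hazard", subcategory="hermetic"),
        PenaltyItem("waste", "waste", subcategory="1-10 mL"),
    ]


def reference_method_items() -> list:
    """Penalty items of the water-based reported comparison method."""
    return [
        PenaltyItem("distilled water", "reagent", pictogram_count=0,
                    signal_word="none", amount_bracket="10-100 mL"),
        PenaltyItem("UV-Vis spectrophotometer", "instrument", subcategory="<=0.1 kWh"),
        PenaltyItem("hermetic procedure", "occupational_hazard", subcategory="hermetic"),
        PenaltyItem("waste", "waste", subcategory="1-10 mL"),
    ]


def load_agree_fixture(path=None) -> tuple[np.ndarray, list]:
    """Synthetic 12-principle score set (see the data file's caveats)."""
    if path is None:
        src = resources.files("specresolve.data").joinpath("agree_synthetic_scores.yaml")
        with resources.as_file(src) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    entries = sorted(raw["principles"], key=lambda e: e["id"])
    scores = np.array([e["score"] for e in entries], dtype=float)
    names = [e["name"] for e in entries]
    return scores, names
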