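"""Message catalog for report texts.

All user-facing strings live here, keyed by section id and message
name, per locale. English ships with the package; further locales can
be registered at run time via :func:`register_locale` without touching
any computation code.
"""

from __future__ import annotations

_CATALOG: dict[str, dict[str, str]] = {
    "en": {
        "meta.title": "Your study at a glance",
        "meta.body": (
            "During the study you were sent {n_scheduled} short surveys. "
            "You completed {n_completed} of them ({percent}%). "
            "The heatmap shows which surveys you completed (filled) and "
            "which you missed (empty)."
        ),
        "continuous.title": "Overview of your ratings",
        "continuous.body": (
            "Each panel shows all your answers for one question on its "
            "1-7 scale, with the vertical bar marking your average. "
            "Points are spread out slightly so overlapping answers stay "
            "visible."
        ),
        "continuous.peak": (
            "On average you reported the most positive feelings on "
            "{best_day} and during the {best_slot} surveys."
        ),
        "categorical.title": "Where you were and what you did",
        "categorical.body": (
            "The bars show how often you selected each answer, as a share "
            "of all your answers to that question."
        ),
        "timeseries.title": "Your feelings over time",
        "timeseries.body": (
            "Dots are your individual answers over the study weeks; the "
            "line is a smoothed trend. Weekends are shaded."
        ),
        "timeseries.gated": (
            "You answered this question fewer than {min_n} times, so we "
            "show your individual answers without a trend line."
        ),
        "recap.title": "Recap: your best and most difficult week",
        "recap.body": (
            "Your most positive week was {best_week} (average positive "
            "mood {best_mean}), your least positive week was {worst_week} "
            "(average {worst_mean}). Across the whole study your average "
            "positive mood was {overall_mean}."
        ),
        "recap.gated": (
            "We could not single out a best and a most difficult week "
            "because too few weeks had enough answers."
        ),
        "network.title": "How your feelings moved together",
        "network.body": (
            "Each line connects two feelings that tended to occur "
            "together at the same moment, after accounting for how you "
            "felt at the previous survey. Solid lines mean the feelings "
            "rose and fell together; dashed lines mean one was high when "
            "the other was low. Thicker lines mean stronger relationships."
        ),
        "network.not_estimated": (
            "This overview is only computed for participants who "
            "completed more than half of the relevant surveys, so it is "
            "not shown for you."
        ),
        "network.failed": (
            "This overview could not be computed reliably from your "
            "answers, so it is not shown."
        ),
        "section.no_data": "Not enough answers were available for this section.",
    }
}


def register_locale(tag: str, messages: dict[str, str]) -> None:
    """Add or extend a locale; missing keys fall back to English."""
    _CATALOG.setdefault(tag, {}).update(messages)


def text(key: str, locale: str = "en", **kwargs) -> str:
    table = _CATALOG.get(locale, {})
    template = table.get(key, _CATALOG["en"][key])
    return template.format(**kwargs) if kwargs else template
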