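"""Map percept reports to the four response categories.

Responses are coded, blind to the eliciting stimulus, into *Auditory*, *Visual*,
*Fusion*, or *Other*, based solely on the initial consonant of the (normalized)
response.  Auditory-only trials are coded identically to their parent McGurk trials:
a report of *da* to the auditory-only *ba* taken from a *ba*/*ga* McGurk pairing is
a Fusion response.

The onset comparison is deliberately coarse: lowercase, strip punctuation, collapse
syllable repetitions, take the leading consonant cluster of the first syllable.
Voiced and voiceless onsets are distinct classes (b != p, d != t, g != k) — this is
what separates Auditory from Fusion in both the ba/ga and pa/ka pairings — and "th"
is its own onset class, so *tha* is not credited as the *ta* fusion percept.
Anything that matches none of the three stimulus-relevant onsets (including
vowel-initial and empty responses) is *Other*.
"""

from __future__ import annotations

import re
from typing import Mapping

import pandas as pd

from .dataset_io import CATEGORIES, StimulusSpec

_PUNCT_RE = re.compile(r"[^a-z\s]")
_ONSET_RE = re.compile(r"^([bcdfghjklmnpqrstvwxz]+)")

#: Default onset-spelling equivalences applied after cluster extraction.  The
#: table maps alternative spellings of an onset to its canonical class; it is
#: intentionally small — coding is by initial consonant, and the only default
#: merges are common English digraph spellings of single onsets.
DEFAULT_ONSET_EQUIVALENCES: Mapping[str, str] = {
    "bh": "b",
    "dh": "d",
    "gh": "g",
    "ph": "f",
    "kh": "k",
}

#: Closed response list of the forced-choice replication experiment.
FORCED_CHOICES = ("BaBa", "GaGa", "DaDa", "Pa", "Ka", "Ta", "ThaTha", "FaFa", "Other")


def response_onset(
    text: str, equivalences: Mapping[str, str] | None = None
) -> str | None:
    """Leading consonant cluster of the first syllable, or None.

    "buh buh" -> "b"; "ThaTha" -> "th"; "ada" -> None (vowel-initial).
    """
    if equivalences is None:
        equivalences = DEFAULT_ONSET_EQUIVALENCES
    cleaned = _PUNCT_RE.sub(" ", text.lower()).strip()
    if not cleaned:
        return None
    first = cleaned.split()[0]
    m = _ONSET_RE.match(first)
    if m is None:
        return None
    onset = m.group(1)
    # "th" is a digraph onset class of its own; otherwise a long cluster is
    # reduced to the digraph/first consonant it starts with.
    if onset.startswith("th"):
        onset = "th"
    elif onset[:2] in equivalences:
        onset = onset[:2]
    else:
        onset = onset[0]
    return equivalences.get(onset, onset)


def _category_onsets(
    stim: StimulusSpec,
    parent: StimulusSpec | None,
    equivalences: Mapping[str, str] | None,
) -> dict[str, str]:
    """(onset -> category) map for one stimulus context.

    For auditory-only stimuli with a McGurk parent, the Visual and Fusion onsets
    come from the parent so that coding matches the parent's trials exactly.
    """
    src = parent if (stim.is_auditory_only and parent is not None) else stim
    mapping: dict[str, str] = {}
    # Later entries never overwrite earlier ones: the Auditory onset wins if a
    # degenerate stimulus shares onsets (cannot happen for McGurk pairings).
    pairs = [
        (stim.auditory_token, "Auditory"),
        (src.visual_token, "Visual"),
        (src.expected_fusion_token, "Fusion"),
    ]
    for token, category in pairs:
        if token is None:
            continue
        onset = response_onset(token, equivalences)
        if onset is not None and onset not in mapping:
            mapping[onset] = category
    return mapping


def code_response(
    raw: str,
    stim: StimulusSpec,
    parent: StimulusSpec | None = None,
    equivalences: Mapping[str, str] | None = None,
) -> str:
    """Code one open-choice response against its eliciting stimulus.

    Deterministic, case/whitespace/repetition-insensitive, and independent of the
    participant and of trial order.  Empty or unmatched responses are *Other*.
    """
    onset = response_onset(raw or "", equivalences)
    if onset is None:
        return "Other"
    return _category_onsets(stim, parent, equivalences).get(onset, "Other")


def code_forced_choice(
    choice: str,
    stim: StimulusSpec,
    parent: StimulusSpec | None = None,
) -> str:
    """Code one closed-list forced choice.

    The choice must come from the replication list; a choice equal (ignoring case
    and whitespace) to the stimulus's auditory/visual/fusion token maps to the
    corresponding category, everything else to *Other*.
    """
    norm = (choice or "").strip()
    allowed = {c.lower(): c for c in FORCED_CHOICES}
    if norm.lower() not in allowed:
        raise ValueError(f"choice {choice!r} not in the closed response list")
    src = parent if (stim.is_auditory_only and parent is not None) else stim
    token = norm.lower()
    if token == stim.auditory_token:
        return "Auditory"
    if src.visual_token is not None and token == src.visual_token:
        return "Visual"
    if src.expected_fusion_token is not None and token == src.expected_fusion_token:
        return "Fusion"
    return "Other"


def code_trials(
    frame: pd.DataFrame,
    stimuli: Mapping[str, StimulusSpec],
    forced_choice: bool = False,
    equivalences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Code the ``raw_response`` column of a trial table.

    Returns a copy with ``coded_category`` filled; parent McGurk stimuli are
    resolved through the registry.  Coding is memoized per (response, stimulus),
    which is exact because coding is blind to everything else.
    """
    out = frame.copy()
    cache: dict[tuple[str, str], str] = {}
    coded = []
    for raw, stim_id in zip(out["raw_response"], out["stimulus_id"]):
        key = (raw, stim_id)
        if key not in cache:
            stim = stimuli[stim_id]
            parent = stimuli.get(stim.parent_id) if stim.parent_id else None
            if forced_choice:
                cache[key] = code_forced_choice(raw, stim, parent)
            else:
                cache[key] = code_response(raw, stim, parent, equivalences)
        coded.append(cache[key])
    out["coded_category"] = pd.Series(coded, index=out.index)
    assert set(out["coded_category"]) <= set(CATEGORIES)
    return out
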