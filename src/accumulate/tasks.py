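"""Task designs for the supported choice/RT paradigms.

A :class:`TaskDesign` records, for each task, the set of trial conditions,
the available response options, which response is correct in each condition,
and the response window after which responses are recorded as omissions.

Two designs ship with the package:

* ``nback`` — an n-back recognition design with ``target``, ``lure`` and
  ``novel`` trial types, ``target``/``nontarget`` responses and a 2-s
  response window.  ``target`` trials require a ``target`` response; lures
  and novel stimuli require ``nontarget``.
* ``numerosity`` — a 2 (stimulus class: many/few) x 2 (difficulty:
  easy/hard) numerosity discrimination with ``many``/``few`` responses and
  a 3-s window.
"""

from __future__ import annotations

from dataclasses import dataclass

OMITTED = "omitted"


@dataclass
class TaskDesign:
    name: str
    conditions: tuple[str, ...]
    responses: tuple[str, ...]
    #: condition -> correct response option
    correct_response: dict[str, str]
    window: float  # response window in seconds
    #: whether LBA thresholds are estimated per response option
    response_specific_thresholds: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in self.conditions if c not in self.correct_response]
        if missing:
            raise ValueError(f"no correct response defined for conditions {missing}")
        bad = [r for r in self.correct_response.values() if r not in self.responses]
        if bad:
            raise ValueError(f"correct responses {bad} are not response options")

    def error_response(self, condition: str) -> str:
        """The incorrect response option for a binary-choice condition."""
        correct = self.correct_response[condition]
        others = [r for r in self.responses if r != correct]
        if len(others) != 1:
            raise ValueError("error_response is only defined for binary choice")
        return others[0]


NBACK = TaskDesign(
    name="nback",
    conditions=("target", "lure", "novel"),
    responses=("target_resp", "nontarget_resp"),
    correct_response={
        "target": "target_resp",
        "lure": "nontarget_resp",
        "novel": "nontarget_resp",
    },
    window=2.0,
    response_specific_thresholds=False,
)

NUMEROSITY = TaskDesign(
    name="numerosity",
    conditions=("many_easy", "few_easy", "many_hard", "few_hard"),
    responses=("many", "few"),
    correct_response={
        "many_easy": "many",
        "many_hard": "many",
        "few_easy": "few",
        "few_hard": "few",
    },
    window=3.0,
    response_specific_thresholds=True,
)

TASKS: dict[str, TaskDesign] = {"nback": NBACK, "numerosity": NUMEROSITY}
# 0-back and 2-back share the same design; accept those names as aliases.
TASKS["nback0"] = NBACK
TASKS["nback2"] = NBACK


def get_task(name: str) -> TaskDesign:
    try:
        return TASKS[name]
    except KeyError:
        raise KeyError(
            f"unknown task {name!r}; available: {sorted(set(TASKS))}"
        ) from None
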