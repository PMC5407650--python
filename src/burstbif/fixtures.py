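"""Named parameter sets for the standard demonstration figures.

Each fixture packages a published rate-constant set (reduced parameters,
k̃i = ki/k4 with k4 = 1) for the burst-Schlögl model, together with the
name of the swept parameter (when the set defines a sweep rather than a
single point) and the default list of burst sizes it is examined at.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import SchloglParams

__all__ = ["ParameterFixture", "fixtures", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class ParameterFixture:
    """A named (possibly partial) reduced-parameter set.

    ``known`` maps reduced parameter names to values; ``sweep`` names the
    parameter left free (None for complete sets).  ``params`` materializes a
    :class:`SchloglParams`, requiring the missing value when there is one.
    """

    name: str
    known: dict
    sweep: str | None
    r_list: tuple[int, ...]
    description: str

    def params(self, r: int | None = None, **overrides) -> SchloglParams:
        kw = dict(self.known)
        kw.update(overrides)
        if self.sweep is not None and self.sweep not in kw:
            raise ValueError(
                f"fixture {self.name!r} sweeps {self.sweep!r}; supply a value, "
                f"e.g. params({self.sweep}=...)"
            )
        return SchloglParams.from_reduced(
            kw["k1"], kw["k2"], kw["k3"], r=self.r_list[0] if r is None else r
        )


_FIXTURES = {
    "fig2": ParameterFixture(
        "fig2", {"k1": 8e6, "k2": 1.33e5}, "k3", (1,),
        "stationary-law comparison sweep over k̃3 (deterministic cusp line)",
    ),
    "fig3": ParameterFixture(
        "fig3", {"k1": 9e6, "k2": 1.5e5, "k3": 720.0}, None, (1,),
        "burst-size sweep: bimodal at r = 1, unimodal at large r",
    ),
    "fig4a": ParameterFixture(
        "fig4a", {"k2": 1.65e5, "k3": 720.0}, "k1", (1, 11, 21, 31, 41),
        "extrema vs k̃1 for growing burst size",
    ),
    "fig4b": ParameterFixture(
        "fig4b", {"k1": 5.33e6, "k3": 800.0}, "k2", (1, 11, 21, 31, 41),
        "extrema vs k̃2 for growing burst size",
    ),
    "fig4c": ParameterFixture(
        "fig4c", {"k1": 8e6, "k2": 1e5}, "k3", (1, 11, 21, 31, 41),
        "extrema vs k̃3 for growing burst size",
    ),
    "fig6": ParameterFixture(
        "fig6", {"k1": 3e6, "k2": 77518.0, "k3": 601.0}, None, (1, 25),
        "burst-induced bistability: one mode at r = 1, two modes at r = 25",
    ),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixtures(name: str) -> ParameterFixture:
    """Look up a named parameter fixture (fig2, fig3, fig4a-c, fig6)."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
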