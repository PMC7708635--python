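"""Dispensing arithmetic for automated HDX labelling robots.

Small closed-form helpers that track protein material and buffer
volumes through the aspirate -> dilute -> label -> quench -> inject
chain of an automated HDX-MS run. They quantify three operating
characteristics of a dispensing method: the fraction of aspirated
protein that reaches the column, the deuterium fraction of the
labelling mix, and the quench-to-total volume ratio (which sets how
much the quench buffer dilutes the sample).

Defaults describe a low-loss method for dilute samples: 5.7 uL
aspirated, 5.2 uL diluted into 98.8 uL of labelling buffer, 99 uL of
the mix transferred into 11 uL of quench solution, and 105 uL injected
through a 100 uL sample loop.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DispensingScheme:
    """Volumes (uL) of one aspirate-to-injection chain."""

    aspirated: float = 5.7          # protein drawn from the vial
    diluted: float = 5.2            # protein carried into the labelling mix
    labelling_buffer: float = 98.8  # deuterated (or protonated) buffer added
    transferred: float = 99.0       # labelling mix moved to the quench vial
    quench: float = 11.0            # quench solution in the vial
    loop: float = 100.0             # sample loop volume (caps the injection)

    def __post_init__(self) -> None:
        for name in ("aspirated", "diluted", "labelling_buffer",
                     "transferred", "quench", "loop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.diluted > self.aspirated:
            raise ValueError("cannot dilute more than was aspirated")
        if self.transferred > self.diluted + self.labelling_buffer:
            raise ValueError("cannot transfer more than the labelling mix")

    @property
    def labelled_volume(self) -> float:
        return self.diluted + self.labelling_buffer

    @property
    def quenched_volume(self) -> float:
        return self.transferred + self.quench


def injected_fraction(scheme: DispensingScheme = DispensingScheme()) -> float:
    """Fraction of the aspirated protein that reaches the column.

    Product of the carry-over at each step: dilution, transfer to the
    quench vial, and injection through the loop (which discards any
    excess over its volume).

    >>> round(100 * injected_fraction())
    79
    """
    injected = min(scheme.loop, scheme.quenched_volume)
    return (scheme.diluted / scheme.aspirated
            * scheme.transferred / scheme.labelled_volume
            * injected / scheme.quenched_volume)


def final_d2o_fraction(scheme: DispensingScheme = DispensingScheme(),
                       buffer_d2o: float = 1.0) -> float:
    """Deuterium fraction of the labelling mix: the D2O-based buffer
    diluted by the protonated protein aliquot.

    >>> round(100 * final_d2o_fraction())
    95
    """
    if not 0 < buffer_d2o <= 1:
        raise ValueError("buffer_d2o must be in (0, 1]")
    return buffer_d2o * scheme.labelling_buffer / scheme.labelled_volume


def quench_volume_ratio(scheme: DispensingScheme = DispensingScheme()) -> float:
    """Quench solution as a fraction of the total quenched volume.

    A small ratio preserves sample concentration; it requires a quench
    buffer concentrated enough to reach the target pH at 1:10.

    >>> round(100 * quench_volume_ratio())
    10
    """
    return scheme.quench / scheme.quenched_volume


def improvement_factor(fraction: float, reference_fraction: float = 0.25) -> float:
    """How many times more material a scheme injects than a reference
    method (e.g. a vendor default that injects 25%)."""
    if reference_fraction <= 0:
        raise ValueError("reference_fraction must be > 0")
    return fraction / reference_fraction
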