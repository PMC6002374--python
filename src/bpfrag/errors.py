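"""Exception hierarchy.

Everything raised on purpose derives from :class:`BpfragError` so callers
(and the CLI) can distinguish domain errors from bugs.
"""


class BpfragError(Exception):
    """Base class for all bpfrag domain errors."""


class StructureParseError(BpfragError):
    """Input text could not be parsed into a molecular graph."""


class UnsupportedElementError(StructureParseError):
    """The structure contains an element outside {C, H, N, O}."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(
            f"unsupported element {element!r}: only C, H, N and O are handled"
        )


class RingBondError(BpfragError):
    """A ring bond was passed where a bridge (acyclic) bond is required."""


class ChannelAbsentError(BpfragError):
    """The requested cleavage channel has no activation energy (or is
    forbidden, e.g. by the even-electron rule or a missing transferable H)."""


class NoAcyliumError(BpfragError):
    """CO loss requested on an ion without a charged carbonyl carbon."""


class TableFormatError(BpfragError):
    """An activation-energy table file is malformed."""


class SpectrumFormatError(BpfragError):
    """An MSP spectrum file is malformed."""


class UnknownFixtureError(BpfragError):
    """Requested a built-in example molecule that does not exist."""
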