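"""Exception hierarchy and CLI exit codes."""


class CoroflowError(Exception):
    """Base class for all coroflow-specific failures."""


class FormatError(CoroflowError):
    """Input file does not match the expected dialect (header, types, keys)."""


class TopologyError(CoroflowError):
    """Vessel tree or circuit graph is structurally invalid (cycle, orphan,
    disconnected ground)."""


class SiteLookupError(CoroflowError):
    """Requested segment id is unknown or is not a measurement site."""


class CalibrationError(CoroflowError):
    """Aortic-outlet calibration is infeasible: coronary flow alone already
    meets or exceeds the target total inflow."""


class StateError(CoroflowError):
    """A solved quantity was requested from an object that does not hold it."""


class UndefinedCorrelationError(CoroflowError):
    """Pearson correlation undefined (zero variance in an input vector)."""


class JoinError(CoroflowError):
    """Site ids in paired input files do not match."""


#: Distinct process exit codes for the CLI, one per failure family.
EXIT_CODES = {
    FormatError: 3,
    TopologyError: 4,
    CalibrationError: 5,
    SiteLookupError: 6,
    JoinError: 7,
    ValueError: 8,
}


def exit_code_for(exc: BaseException) -> int:
    for cls, code in EXIT_CODES.items():
        if isinstance(exc, cls):
            return code
    return 1
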