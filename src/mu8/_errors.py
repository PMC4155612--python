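"""Exception hierarchy shared across the package.

Exit-code convention for the CLI: input/format problems exit 2,
mapping/assembly problems exit 3.
"""


class Mu8Error(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputFormatError(Mu8Error):
    """Malformed or unreadable input (AAindex records, alignments, PDB, config)."""

    exit_code = 2


class MappingError(Mu8Error):
    """Sequence/structure mapping or cross-component assembly failure."""

    exit_code = 3
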