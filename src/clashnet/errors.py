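"""Exception hierarchy.

Two error families matter to callers: malformed inputs (bad matrices,
unknown node ids, unparseable files) and evaluations that are undefined
(e.g. an AUC requested where only one class is present). The CLI maps
them to exit codes 2 and 3 respectively.
"""


class ClashError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(ClashError):
    """An input object or file violates a documented precondition."""


class EvaluationUndefinedError(ClashError):
    """A performance metric is undefined for the given inputs."""
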