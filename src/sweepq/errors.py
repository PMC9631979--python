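"""Exception hierarchy shared by all sweepq backends."""


class SweepqError(Exception):
    """Base class for all sweepq errors."""


class SchemaError(SweepqError):
    """The parameter table violates its schema (missing required columns,
    duplicate job ids, or a record whose attributes do not match the header)."""


class NotFoundError(SweepqError):
    """A job id, attribute, or stored object does not exist."""


class BackendUnavailableError(SweepqError):
    """The backing store cannot be reached (e.g. the file was deleted)."""


class ContentionError(SweepqError):
    """An exclusive lock could not be acquired within the timeout.

    Retryable: the table itself is intact, another worker merely held the
    lock for too long.
    """


class UnresolvedPathError(SweepqError):
    """An XML element path did not resolve to any element in the document."""


class StorageError(SweepqError):
    """A remote-storage transfer failed."""


class ConflictError(StorageError):
    """A rename target already exists."""
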