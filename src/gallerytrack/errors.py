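"""Exception hierarchy for gallerytrack.

All errors raised by the library derive from :class:`GalleryTrackError`,
so callers (and the CLI) can catch one base class.
"""

from __future__ import annotations


class GalleryTrackError(Exception):
    """Base class for all gallerytrack errors."""


class MalformedNameError(GalleryTrackError):
    """An image filename does not follow the ``<groupid>_<serial>.<ext>`` grammar."""


class ProjectFormatError(GalleryTrackError):
    """A project file is unreadable, truncated, or structurally invalid."""


class ProjectVersionError(ProjectFormatError):
    """A project file declares a format version this library cannot read."""


class DegeneratePolylineError(GalleryTrackError):
    """A polyline operation was given fewer than two points."""


class CalibrationError(GalleryTrackError):
    """The scale line has zero pixel length or the real-world length is invalid."""


class UnresolvableSkipError(GalleryTrackError):
    """The first image of a group is marked skipped, so there is nothing to copy forward."""


class ClassificationError(GalleryTrackError):
    """Gallery identity assignment failed; carries the offending image identity."""

    def __init__(self, message: str, group_id: str | None = None,
                 serial: int | None = None, gallery_ids: tuple[str, ...] = ()):
        super().__init__(message)
        self.group_id = group_id
        self.serial = serial
        self.gallery_ids = gallery_ids


class NetworkError(GalleryTrackError):
    """Network reconstruction was asked to run on incompletely classified galleries."""
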