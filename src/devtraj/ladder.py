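"""Ordered developmental age ladders and their stages.

An :class:`AgeLadder` is the ordered set of sampled ages, with the last
label designated the adult endpoint.  A *stage* is a consecutive pair of
ages; the staging used for trajectory classification may be a configurable
subset of all consecutive pairs (e.g. postnatal stages only).
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The study design this package was built around: two embryonic and six
#: postnatal ages, with P65 as the adult reference.
DEFAULT_AGES = ("E16", "E18", "P0", "P4", "P10", "P18", "P28", "P65")


@dataclass(frozen=True)
class AgeLadder:
    """Ordered age labels with a designated adult endpoint.

    Parameters
    ----------
    labels
        Ordered, unique age labels from youngest to oldest.
    stage_set
        Ordered consecutive ``(younger, older)`` pairs used for staging.
        Defaults to every consecutive pair.  For the default 8-age ladder
        the conventional choice is the five postnatal stages
        ``P0→P4 … P28→P65``, excluding the embryonic intervals.
    """

    labels: tuple[str, ...]
    stage_set: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("AgeLadder needs at least two age labels")
        if len(set(labels)) != len(labels):
            raise ValueError("age labels must be unique")
        stages = tuple(tuple(p) for p in self.stage_set)
        if not stages:
            stages = tuple(zip(labels[:-1], labels[1:]))
        for young, old in stages:
            i, j = labels.index(young), labels.index(old)
            if j != i + 1:
                raise ValueError(
                    f"stage ({young}, {old}) is not a consecutive pair on the ladder"
                )
        object.__setattr__(self, "stage_set", stages)

    @property
    def adult(self) -> str:
        """The terminal (adult) label."""
        return self.labels[-1]

    @property
    def n_stages(self) -> int:
        return len(self.stage_set)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"age label {label!r} not on ladder {self.labels}") from None

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    @classmethod
    def default(cls) -> "AgeLadder":
        """The 8-age E16→P65 ladder staged over the five postnatal intervals."""
        postnatal = ("P0", "P4", "P10", "P18", "P28", "P65")
        stages = tuple(zip(postnatal[:-1], postnatal[1:]))
        return cls(DEFAULT_AGES, stages)
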