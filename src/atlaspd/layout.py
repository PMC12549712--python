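"""Channel montage and anatomical region map for the 22-channel prefrontal probe."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ChannelLayout", "REGIONS", "CHANNEL_IDS", "default_layout"]

#: Anatomical partition of the 22 channels over the prefrontal cortex.
REGIONS: dict[str, tuple[str, ...]] = {
    "L-FPC": ("CH01", "CH05", "CH06", "CH10"),
    "R-FPC": ("CH04", "CH08", "CH09", "CH13"),
    "mFPC": ("CH02", "CH03", "CH07", "CH11", "CH12", "CH16"),
    "L-DLPFC": ("CH14", "CH15", "CH19"),
    "R-DLPFC": ("CH17", "CH18", "CH22"),
    "BA8": ("CH20", "CH21"),
}

CHANNEL_IDS: tuple[str, ...] = tuple(f"CH{i:02d}" for i in range(1, 23))


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel list with a channel -> anatomical region map.

    The default montage has 22 channels at 3 cm source-detector separation
    covering bilateral and medial frontal polar cortex, bilateral DLPFC,
    and Brodmann area 8.
    """

    channel_ids: tuple[str, ...] = CHANNEL_IDS
    region_of: dict[str, str] = field(default_factory=lambda: {
        ch: region for region, chans in REGIONS.items() for ch in chans
    })
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("duplicate channel ids")
        missing = [ch for ch in self.channel_ids if ch not in self.region_of]
        if missing:
            raise ValueError(f"channels without a region: {missing}")
        if self.source_detector_distance_cm <= 0:
            raise ValueError("source-detector distance must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch in self.channel_ids:
            r = self.region_of[ch]
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def region_channels(self, region: str) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_ids if self.region_of[ch] == region)

    def index_of(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)


def default_layout() -> ChannelLayout:
    """The 22-channel prefrontal montage with its six-region partition."""
    layout = ChannelLayout()
    assert layout.n_channels == 22
    return layout
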