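"""Multichannel image stacks: blank-cycle correction and normalization.

Cyclic-immunofluorescence runs acquire, besides the marker channels, a blank
cycle at each imaging wavelength.  The blank image captures autofluorescence
and camera background; subtracting it and dividing by its standard deviation
puts channels acquired at different wavelengths (with different dynamic
ranges) on a common scale before per-channel percentile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from renimap.errors import ConfigError

__all__ = ["ChannelStack", "background_correct", "percentile_normalize", "normalize_stack"]


@dataclass
class ChannelStack:
    """Named 2-D marker channels plus their blank-cycle counterparts.

    Parameters
    ----------
    channels
        Mapping marker name -> 2-D float array (arbitrary intensity units).
    blank_channels
        Mapping wavelength-group name -> 2-D float array.
    pixel_size
        Physical pixel size in micrometres per pixel.
    channel_to_blank
        Assigns each marker channel its blank counterpart.
    """

    channels: dict[str, np.ndarray]
    blank_channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 0.1507
    channel_to_blank: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        shapes = {a.shape for a in self.channels.values()}
        shapes |= {a.shape for a in self.blank_channels.values()}
        if len(shapes) > 1:
            raise ConfigError(f"all channels must share one shape, got {shapes}")
        if self.blank_channels:
            for name in self.channels:
                blank = self.channel_to_blank.get(name)
                if blank is None or blank not in self.blank_channels:
                    raise ConfigError(f"channel {name!r} has no blank counterpart")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def background_correct(stack: ChannelStack) -> ChannelStack:
    """Subtract each channel's blank-cycle image and standardize its scale.

    Per channel: ``out = clip(channel - blank, 0) / sd(blank)`` elementwise,
    with the population standard deviation of the blank image.  Negative
    differences are clipped at zero (fluorescence is non-negative).  Blank
    channels pass through unchanged.

    Raises
    ------
    ConfigError
        If a blank image is constant (sd = 0), naming the channel.
    """
    corrected = {}
    for name, chan in stack.channels.items():
        blank = stack.blank_channels[stack.channel_to_blank[name]]
        sd = float(np.std(blank))
        if sd == 0:
            raise ConfigError(f"blank image for channel {name!r} has zero standard deviation")
        corrected[name] = np.clip(chan.astype(float) - blank, 0.0, None) / sd
    return ChannelStack(
        channels=corrected,
        blank_channels=dict(stack.blank_channels),
        pixel_size=stack.pixel_size,
        channel_to_blank=dict(stack.channel_to_blank),
    )


def percentile_normalize(channel: np.ndarray, p: float = 99.0) -> np.ndarray:
    """Min-max normalize a channel to its *p*-th percentile, into [0, 1].

    ``out = (x - min) / (P_p - min)`` with values above the percentile clipped
    to 1.  Percentiles use linear interpolation between order statistics.  A
    constant channel maps to all zeros.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        raise ConfigError("cannot normalize an empty channel")
    lo = x.min()
    hi = np.percentile(x, p)
    if hi == lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def normalize_stack(stack: ChannelStack, p: float = 99.0) -> ChannelStack:
    """Apply :func:`percentile_normalize` to every marker channel."""
    return ChannelStack(
        channels={k: percentile_normalize(v, p) for k, v in stack.channels.items()},
        blank_channels=dict(stack.blank_channels),
        pixel_size=stack.pixel_size,
        channel_to_blank=dict(stack.channel_to_blank),
    )
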