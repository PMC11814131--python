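import pandas as pd

from mhwbloom import ExtremeEvent


def make_event(variable, polarity, start, end):
    """Minimal event stub with a real date span and placeholder intensities."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    return ExtremeEvent(
        variable=variable,
        polarity=polarity,
        start=start,
        end=end,
        duration=(end - start).days + 1,
        max_intensity=1.0 if polarity == "high" else -1.0,
        mean_intensity=0.5 if polarity == "high" else -0.5,
        cumulative_intensity=1.0,
        peak_date=start,
    )
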