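import numpy as np
import pandas as pd
import pytest

from flownoise import FlowSeries


@pytest.fixture
def make_series():
    """Build a FlowSeries from a value array with a contiguous date axis."""

    def _make(values, start="1980-01-01", gage_id="test"):
        values = np.asarray(values, dtype=float)
        dates = pd.date_range(start, periods=len(values), freq="D")
        return FlowSeries(gage_id=gage_id, dates=dates, values=values)

    return _make


RDB_HEADER = (
    "# U.S. Geological Survey\n"
    "# Data for the following 1 site(s) are contained in this file\n"
    "#  USGS 01234567 EXAMPLE CREEK\n"
    "# retrieved: synthetic fixture\n"
    "#\n"
    "agency_cd\tsite_no\tdatetime\t12345_00060_00003\t12345_00060_00003_cd\n"
    "5s\t15s\t20d\t14n\t10s\n"
)


@pytest.fixture
def make_rdb(tmp_path):
    """Write a toy NWIS daily-values RDB file and return its path."""

    def _make(rows, comments=True, name="gage.rdb"):
        body = "".join(
            f"USGS\t01234567\t{date}\t{value}\t{code}\n" for date, value, code in rows
        )
        text = RDB_HEADER if comments else "".join(RDB_HEADER.splitlines(keepends=True)[5:])
        path = tmp_path / name
        path.write_text(text + body)
        return path

    return _make


def oracle_noise_color(x):
    """Independent log-log slope estimate: scipy periodogram + linregress.

    Shares nothing with flownoise's estimator beyond numpy; used as the
    second route in dual-route recovery checks.
    """
    from scipy.signal import periodogram as sp_periodogram
    from scipy.stats import linregress

    x = np.asarray(x, float)
    f, P = sp_periodogram(x - x.mean(), detrend=False, window="boxcar")
    keep = (f > 0) & (P > 0)
    fit = linregress(np.log10(f[keep]), np.log10(P[keep]))
    return -fit.slope
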