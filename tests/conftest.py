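import numpy as np
import pytest

from frugalspiro.acquisition_model import AdcSpec, DividerSpec, SensorSpec
from frugalspiro.breath_pipeline import FlowTrace, PipelineConfig
from frugalspiro.venturi_core import FluidProperties, TubeGeometry


@pytest.fixture
def geom():
    """As-printed tube: 27.8 mm entrance, 9.8 mm throat."""
    return TubeGeometry()


@pytest.fixture
def fluid():
    return FluidProperties()


@pytest.fixture
def sensor():
    return SensorSpec()


@pytest.fixture
def divider():
    return DividerSpec()


@pytest.fixture
def adc():
    return AdcSpec()


@pytest.fixture
def pipeline_cfg():
    return PipelineConfig()


def make_flow_trace(flow_lpm, sampling_rate=1000.0):
    """FlowTrace straight from a flow array, bypassing the electronics."""
    flow_lpm = np.asarray(flow_lpm, dtype=float)
    t = np.arange(flow_lpm.size) / sampling_rate
    return FlowTrace(
        flow_lpm=flow_lpm,
        time_s=t,
        sampling_rate=sampling_rate,
        offset_voltage_used=0.2,
    )
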