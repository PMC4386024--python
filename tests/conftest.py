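"""Shared fixtures: schedules and a small 'hot' synthetic session.

The hot session raises the behavioral response probability far above the
naturalistic model so a 90-epoch session contains enough evoked
convergences to exercise the event-triggered analyses.
"""

import numpy as np
import pytest

from preyscope.behavior import classify_evoked, detect_convergent_saccades
from preyscope.stimulus import generate_schedule
from preyscope.synthdata import (
    BehaviorParams,
    GeometryParams,
    assign_assembly_events,
    generate_eye_traces,
    generate_fluorescence,
    generate_population,
)


@pytest.fixture(scope="session")
def schedule5():
    return generate_schedule(n_planes=1, reps=5, seed=0)


@pytest.fixture(scope="session")
def hot_params():
    p = BehaviorParams()
    # drive large/dark stimuli to ~40-50% response probability, leaving
    # enough non-response trials of each stimulus for the event-triggered
    # comparisons
    p.logistic_coeffs = {
        "intercept": -4.5,
        "size": 1.8,
        "polarity": 2.2,
        "speed:size:polarity": 0.5,
    }
    p.spontaneous_rate_hr = 8.0
    return p


@pytest.fixture(scope="session")
def hot_schedule():
    return generate_schedule(n_planes=1, reps=8, seed=0)


@pytest.fixture(scope="session")
def hot_session(hot_schedule, hot_params):
    """Schedule + eyes + ROIs + traces with many evoked convergences and
    several planted assemblies."""
    trace, true_events = generate_eye_traces(hot_schedule, hot_params, seed=11)
    geometry = GeometryParams(n_rois=260, n_fish=8)
    from preyscope.synthdata import DEFAULT_MIXTURE

    mixture = dict(DEFAULT_MIXTURE)
    mixture["assembly"] = 0.30
    mixture["nonresponsive"] = 0.24
    rois, truth = generate_population(geometry, mixture, seed=12)
    assign_assembly_events(truth, true_events)
    traces = generate_fluorescence(
        rois, truth, hot_schedule, true_events, seed=13
    )
    detected = detect_convergent_saccades(trace)
    classify_evoked(detected, hot_schedule)
    return {
        "schedule": hot_schedule,
        "eye_trace": trace,
        "true_events": true_events,
        "rois": rois,
        "truth": truth,
        "traces": traces,
        "detected": detected,
    }
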