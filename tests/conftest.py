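import numpy as np
import pytest

from neurocalnet import synthetic as syn


def merged_truth_times(times, min_sep=1.0):
    """Group planted event times closer than the detector dead time."""
    groups = []
    for t in np.sort(np.asarray(times)):
        if groups and t - groups[-1][-1] < min_sep:
            groups[-1].append(t)
        else:
            groups.append([t])
    return groups


def detection_scores(events, ground_truth, frame_rate, tol=0.5, min_sep=1.0):
    """(recall, precision) of detected transients against planted times.

    Recall counts a dead-time-merged truth group as found when any
    detection lands within ``tol`` seconds of any member; precision
    counts a detection as correct when it lands within ``tol`` of any
    raw truth time.
    """
    tp_det = n_det = matched = n_truth = 0
    for i, times in enumerate(ground_truth.spike_times):
        det = [ev.onset_frame / frame_rate for ev in events if ev.neuron == i]
        n_det += len(det)
        groups = merged_truth_times(times, min_sep)
        n_truth += len(groups)
        for grp in groups:
            if any(any(abs(d - t) <= tol for t in grp) for d in det):
                matched += 1
        for d in det:
            if any(abs(d - t) <= tol for t in times):
                tp_det += 1
    recall = matched / n_truth if n_truth else 1.0
    precision = tp_det / n_det if n_det else 1.0
    return recall, precision


@pytest.fixture(scope="session")
def default_population():
    """One default-condition simulated session reused across tests."""
    traces, truth = syn.gen_calcium_traces(syn.CalciumSimConfig(seed=7))
    return traces, truth
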