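"""Shared test utilities (importable because pytest puts tests/ on sys.path)."""

from sklearn.linear_model import ElasticNet
from sklearn.neighbors import KNeighborsRegressor
from xgboost import XGBRegressor

from cellfactory.ensemble import RegressorSpec


def cheap_specs(seed=0):
    """Three fast base learners for pipeline-shaped tests."""
    return [
        RegressorSpec("elastic_net", ElasticNet(max_iter=2000, random_state=seed),
                      {"alpha": [0.01, 0.1]}),
        RegressorSpec("gradient_boosted_trees",
                      XGBRegressor(n_estimators=60, max_depth=3, n_jobs=1,
                                   random_state=seed, verbosity=0), {}),
        RegressorSpec("knn", KNeighborsRegressor(), {"n_neighbors": [5]}),
    ]
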