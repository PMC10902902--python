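"""Run a trained forecaster on simulated memristive crossbar hardware.

Every weight matrix is programmed once into a differential conductance
pair; forward passes route all matrix products through the analog
arrays.  Ideal crossbars reproduce the digital forecasts exactly;
quantization and programming noise degrade them progressively.
"""

import numpy as np

from memlstm import SynthConfig, XbarConfig, generate, make_windows, rmse, to_memristive
from memlstm.experiments import PreprocessingConfig, prepare_split
from memlstm.lstm import TrainConfig, train

prep = PreprocessingConfig()
train_rec, test_rec, _ = prepare_split(generate(SynthConfig(seed=7)).recording, prep)
hyper = TrainConfig(hidden=32, feature_dim=32, max_epochs=12,
                    batch_size=128, patience=5)
network, _ = train(make_windows(train_rec, prep.window), hyper, seed=7)

ds = make_windows(test_rec, prep.window)
digital = network.predict_batch(ds.inputs)
print(f"digital test RMSE:            {rmse(ds.targets, digital):.4f}")

ideal = to_memristive(network, XbarConfig(levels=None))
diff = np.max(np.abs(ideal.predict_batch(ds.inputs) - digital))
print(f"ideal crossbar max deviation: {diff:.1e}")

quant = to_memristive(network, XbarConfig(levels=256))
print(f"256-level quantized RMSE:     {rmse(ds.targets, quant.predict_batch(ds.inputs)):.4f}")

for sigma in (0.1, 0.3):
    vals = [
        rmse(ds.targets,
             to_memristive(network, XbarConfig(levels=256, noise_sigma=sigma,
                                               seed=k + 1)).predict_batch(ds.inputs))
        for k in range(10)
    ]
    print(f"noise sigma={sigma}: mean RMSE    {np.mean(vals):.4f} over 10 seeds")

# Differential encoding is exact, so analog inference is free until real
# nonidealities enter: 8-bit programming costs almost nothing here, while
# multiplicative conductance noise dominates quickly.
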