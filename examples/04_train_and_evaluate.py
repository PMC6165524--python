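"""Train the stacked peephole LSTM and evaluate on held-out windows.

Simulates separate training and test recordings, extracts 100-feature
vectors, trains the 5-layer x 15-unit LSTM at learning rate 0.003 and
prints the confusion matrix and metric set.
"""

import harspec as h
from harspec.lstm import LstmConfig

specs = list(h.default_specs().values())
train_fs = h.build_feature_set(
    h.make_dataset(specs, 5, 50.0, seed=100, duration_s=18.0))
test_fs = h.build_feature_set(
    h.make_dataset(specs, 3, 50.0, seed=200, duration_s=18.0))
print(f"train rows {len(train_fs)}, test rows {len(test_fs)}")

cfg = LstmConfig(hidden_units=15, stacked_layers=5, learning_rate=0.003,
                 max_epochs=300, seed=0)
model, history = h.train(train_fs, cfg)
print(f"stopped after {len(history)} epochs, "
      f"final training loss {history[-1]['loss']:.4f}")

cm = h.confusion_matrix(test_fs.labels, h.predict(model, test_fs))
print("confusion matrix (rows true ST/SI/WA, columns predicted):")
print(cm.to_frame())
report = h.precision_recall_f1(cm)
print(f"held-out accuracy {report.accuracy:.2f}%  "
      f"macro f1 {report.macro_f1:.2f}%")

# On clean synthetic data the three activities are spectrally well
# separated, so held-out accuracy is at or near 100 %.
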