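name,params_millions
MobileNetV2,3.4
DenseNet-121,8.0
ResNet-50,25.6
ViT-small,22.1
CoAtNet,25.0
VGG16,138.4
VGG19,143.7
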