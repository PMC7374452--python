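scale,group,n,mean,sd
self_perception,control,20,22.25,3.40
self_perception,experimental,25,20.36,5.60
feeding,control,20,27.00,3.64
feeding,experimental,25,26.40,2.66
wellness,control,20,40.75,5.73
wellness,experimental,25,39.32,7.03
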