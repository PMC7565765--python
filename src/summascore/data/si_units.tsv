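# Measurement-unit symbols: symbol, dimension.  A number adjacent to one
# of these marks a raw (untransformed) measurement mention.
°C	temperature
°F	temperature
mmHg	pressure
kPa	pressure
kg	mass
g	mass
mg	mass
µg	mass
cm	length
mm	length
ml	volume
dl	volume
l	volume
mmol	amount
bpm	rate
%	fraction
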