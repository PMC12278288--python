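country,cluster
Algeria,1
Antigua and Barbuda,1
Armenia,1
Azerbaijan,1
Bahamas,1
Barbados,1
Belize,1
Bolivia,1
Bosnia and Herzegovina,1
Bulgaria,1
Chile,1
China,1
Colombia,1
Costa Rica,1
Cuba,1
Dominican Republic,1
Ecuador,1
El Salvador,1
Fiji,1
Gabon,1
Georgia,1
Grenada,1
Guyana,1
Iran,1
Jamaica,1
Japan,1
Kiribati,1
Kuwait,1
Kyrgyzstan,1
Lebanon,1
Malaysia,1
Maldives,1
Malta,1
Mauritius,1
Mexico,1
Moldova,1
Morocco,1
Myanmar,1
North Macedonia,1
Oman,1
Panama,1
Papua New Guinea,1
Paraguay,1
Peru,1
Qatar,1
Saint Lucia,1
Saint Vincent and the Grenadines,1
Samoa,1
Saudi Arabia,1
Serbia,1
Seychelles,1
South Africa,1
Suriname,1
Tajikistan,1
Trinidad and Tobago,1
Tunisia,1
Turkmenistan,1
Ukraine,1
United Arab Emirates,1
Uzbekistan,1
Vietnam,1
Argentina,2
Australia,2
Austria,2
Bahrain,2
Belarus,2
Belgium,2
Brazil,2
Canada,2
Croatia,2
Cyprus,2
Czechia,2
Denmark,2
Estonia,2
Finland,2
France,2
Germany,2
Greece,2
Hungary,2
Iceland,2
Ireland,2
Israel,2
Italy,2
Kazakhstan,2
Latvia,2
Lithuania,2
Luxembourg,2
Mongolia,2
Montenegro,2
Netherlands,2
New Zealand,2
Norway,2
Portugal,2
Romania,2
Russia,2
Slovakia,2
Slovenia,2
Spain,2
Sweden,2
Switzerland,2
United Kingdom,2
United States,2
Uruguay,2
Afghanistan,3
Angola,3
Bangladesh,3
Benin,3
Bhutan,3
Botswana,3
Burkina Faso,3
Burundi,3
Cambodia,3
Cameroon,3
Cape Verde,3
Central African Republic,3
Chad,3
Comoros,3
Congo,3
Cote d'Ivoire,3
Democratic Republic of Congo,3
Djibouti,3
East Timor,3
Egypt,3
Eswatini,3
Ethiopia,3
Gambia,3
Ghana,3
Guatemala,3
Guinea,3
Guinea-Bissau,3
Haiti,3
Honduras,3
India,3
Indonesia,3
Iraq,3
Jordan,3
Kenya,3
Laos,3
Lesotho,3
Liberia,3
Madagascar,3
Malawi,3
Mali,3
Mauritania,3
Mozambique,3
Namibia,3
Nepal,3
Nicaragua,3
Niger,3
Nigeria,3
Pakistan,3
Philippines,3
Rwanda,3
Sao Tome and Principe,3
Senegal,3
Sierra Leone,3
Solomon Islands,3
South Sudan,3
Sri Lanka,3
Sudan,3
Tanzania,3
Thailand,3
Togo,3
Uganda,3
Vanuatu,3
Venezuela,3
Zambia,3
Zimbabwe,3
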